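"""Variant records, VCF input, and the labeling rules for building datasets.

Positives come from intersecting two variant collections (e.g. GWAS hits
with significant eQTLs); negatives come either from an association table
filtered on P-value and allele frequency, or from curated sets built around
the positives (nearby non-conserved common variants, or random genomic
positions away from any positive).

Coordinates are 1-based and fully closed, as in VCF. Variant identity is
the tuple (chrom, pos, ref, alt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "VariantRecord", "LabeledDataset", "VcfParseError", "ValidationError",
    "read_vcf", "write_vcf", "intersect_positive", "select_negatives",
    "split_dataset", "curated_negative_candidates", "random_genome_negatives",
]

_VALID_BASES = frozenset("ACGT")

VariantKey = tuple[str, int, str, str]


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when records are missing required annotations."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic genomic variant with optional per-variant annotations.

    ``p_value`` and ``af`` carry association statistics (e.g. from an eQTL
    table); ``conservation`` carries a phastCons-style score in [0, 1].
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."
    p_value: float | None = None
    af: float | None = None
    conservation: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(
                    f"allele {allele!r} is not a non-empty A/C/G/T string"
                )
        if self.af is not None and not (0.0 < self.af < 1.0):
            raise ValueError(f"af must lie in (0, 1), got {self.af}")
        if self.conservation is not None and not (0.0 <= self.conservation <= 1.0):
            raise ValueError(
                f"conservation must lie in [0, 1], got {self.conservation}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class LabeledDataset:
    """Variant records with binary labels (1 = functional/positive)."""

    records: list[VariantRecord]
    labels: np.ndarray
    matrix_link: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.records):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        keys = self.keys()
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant keys in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> list[VariantKey]:
        return [r.key for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "ref": [r.ref for r in self.records],
                "alt": [r.alt for r in self.records],
                "id": [r.id for r in self.records],
                "label": self.labels,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "LabeledDataset":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        records = [
            VariantRecord(row.chrom, int(row.pos), row.ref, row.alt, str(row.id))
            for row in df.itertuples()
        ]
        return cls(records, df["label"].to_numpy())


def read_vcf(path) -> list[VariantRecord]:
    """Read a VCF file into a list of biallelic :class:`VariantRecord`.

    Multi-allelic sites are split into one record per ALT allele, all
    sharing (chrom, pos, ref). Symbolic or non-ACGT alleles are rejected.
    """
    path = str(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: not a parseable VCF (missing or bad header): {exc}") from exc

    records: list[VariantRecord] = []
    line_no = 0  # counts data records, for error messages
    try:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            line_no += 1
            for alt in rec.alts or ():
                try:
                    records.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            id=rec.id or ".",
                        )
                    )
                except ValueError as exc:
                    raise VcfParseError(
                        f"{path}: bad variant at data line {line_no}: {exc}"
                    ) from exc
    except OSError as exc:
        raise VcfParseError(
            f"{path}: malformed data line {line_no + 1}: {exc}"
        ) from exc
    finally:
        vcf.close()
    return records


def write_vcf(variants: Sequence[VariantRecord], path) -> None:
    """Write a minimal VCF 4.2 file, coordinate-sorted within chromosome."""
    chroms: dict[str, None] = {}
    for v in variants:
        chroms.setdefault(v.chrom, None)
    order = {c: i for i, c in enumerate(sorted(chroms))}
    rows = sorted(variants, key=lambda v: (order[v.chrom], v.pos, v.ref, v.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in rows:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\n"
            )


def intersect_positive(
    set_a: Iterable[VariantKey], set_b: Iterable[VariantKey]
) -> LabeledDataset:
    """Variants present in both key sets, all labeled positive.

    Mirrors constructing the positive class as the intersection of a
    disease-association catalogue with a significant-eQTL table. Output
    order is deterministic (sorted by key).
    """
    common = sorted(set(set_a) & set(set_b))
    records = [VariantRecord(c, p, r, a) for c, p, r, a in common]
    return LabeledDataset(records, np.ones(len(records), dtype=int))


def _require_columns(table: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"association table lacks columns {missing}")


def select_negatives(
    table: pd.DataFrame, p_min: float = 0.1, af_min: float = 0.3
) -> LabeledDataset:
    """Rows with P-value > ``p_min`` and allele frequency > ``af_min``.

    Both inequalities are strict; boundary rows are excluded. Rows with a
    missing P-value or AF fail validation (the offending keys are listed).
    """
    _require_columns(table, ["chrom", "pos", "ref", "alt", "p_value", "af"])
    bad = table[table["p_value"].isna() | table["af"].isna()]
    if len(bad):
        keys = [
            (r.chrom, int(r.pos), r.ref, r.alt) for r in bad.itertuples()
        ]
        raise ValidationError(f"rows missing P-value or AF: {keys}")
    kept = table[(table["p_value"] > p_min) & (table["af"] > af_min)]
    records = [
        VariantRecord(
            r.chrom, int(r.pos), r.ref, r.alt,
            getattr(r, "id", "."),
            p_value=float(r.p_value), af=float(r.af),
        )
        for r in kept.itertuples()
    ]
    return LabeledDataset(records, np.zeros(len(records), dtype=int))


def split_dataset(
    ds: LabeledDataset, test_frac: float = 0.2, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Shuffle and split into train/test; the test set is never trained on.

    The test size is round-half-up of ``test_frac * len(ds)``; shuffling is
    a plain uniform permutation driven only by ``seed`` (unstratified).
    """
    if not (0.0 < test_frac < 1.0):
        raise ValueError(f"test_frac must lie in (0, 1), got {test_frac}")
    if len(ds) < 2:
        raise ValueError("need at least 2 records to split")
    n = len(ds)
    n_test = int(np.floor(test_frac * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    def take(idx: np.ndarray) -> LabeledDataset:
        return LabeledDataset(
            [ds.records[i] for i in idx], ds.labels[idx]
        )

    return take(train_idx), take(test_idx)


def curated_negative_candidates(
    positives: Sequence[VariantRecord],
    pool: Sequence[VariantRecord],
    window: int = 1000,
    cons_max: float = 0.5,
    af_min: float = 0.3,
) -> LabeledDataset:
    """Curated negatives: pool variants near a positive but unlikely functional.

    Retains pool variants on the same chromosome as some positive with
    distance <= ``window`` (inclusive), conservation < ``cons_max`` (strict)
    and AF > ``af_min`` (strict). Variants that are themselves positives are
    never retained. Pool records must carry conservation and AF.
    """
    missing = [v.key for v in pool if v.conservation is None or v.af is None]
    if missing:
        raise ValidationError(f"pool variants missing conservation or AF: {missing}")
    pos_keys = {p.key for p in positives}
    by_chrom: dict[str, list[int]] = {}
    for p in positives:
        by_chrom.setdefault(p.chrom, []).append(p.pos)
    kept = []
    for v in pool:
        if v.key in pos_keys:
            continue
        near = any(
            abs(v.pos - p_pos) <= window for p_pos in by_chrom.get(v.chrom, ())
        )
        if near and v.conservation < cons_max and v.af > af_min:
            kept.append(v)
    return LabeledDataset(kept, np.zeros(len(kept), dtype=int))


def random_genome_negatives(
    n: int,
    chrom_lengths: dict[str, int],
    positives: Sequence[VariantRecord],
    min_dist: int = 1000,
    seed: int = 0,
    max_attempts_per_site: int = 1000,
) -> LabeledDataset:
    """Negatives at random genomic positions away from every positive.

    Chromosomes are sampled proportionally to length, positions uniformly;
    draws within ``min_dist`` of any positive (same chromosome) are
    rejected. Alleles are drawn uniformly from the four bases. Raises if
    the rejection loop exceeds ``max_attempts_per_site * n`` attempts.
    """
    if not chrom_lengths:
        raise ValueError("chrom_lengths must be non-empty")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    pos_by_chrom: dict[str, np.ndarray] = {}
    for p in positives:
        pos_by_chrom.setdefault(p.chrom, [])
    for p in positives:
        pos_by_chrom[p.chrom].append(p.pos)  # type: ignore[union-attr]
    pos_by_chrom = {c: np.asarray(v) for c, v in pos_by_chrom.items()}

    bases = np.array(list("ACGT"))
    records: list[VariantRecord] = []
    seen: set[VariantKey] = set()
    attempts = 0
    cap = max_attempts_per_site * max(n, 1)
    while len(records) < n:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"could not place {n} negatives >= {min_dist} bp from "
                f"positives after {cap} attempts"
            )
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
        near = pos_by_chrom.get(chrom)
        if near is not None and near.size and np.abs(near - pos).min() < min_dist:
            continue
        ref, alt = rng.choice(bases, size=2, replace=False)
        rec = VariantRecord(chrom, pos, str(ref), str(alt))
        if rec.key in seen:
            continue
        seen.add(rec.key)
        records.append(rec)
    return LabeledDataset(records, np.zeros(len(records), dtype=int))
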