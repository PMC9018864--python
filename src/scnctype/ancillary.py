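"""Small self-contained measures: the INSM1 H-score and the somatic
variant filter."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "IhcRecord",
    "VariantRecord",
    "insm1_hscore",
    "filter_variants",
    "read_variants",
    "write_variants",
]

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "vaf", "tumor_depth", "normal_depth"]


@dataclass
class IhcRecord:
    """Percentages of weakly, moderately and strongly stained nuclei."""

    pct_weak: float
    pct_moderate: float
    pct_strong: float

    def __post_init__(self) -> None:
        for name in ("pct_weak", "pct_moderate", "pct_strong"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} = {v} outside [0, 100]")
        if self.pct_weak + self.pct_moderate + self.pct_strong > 100:
            raise ValueError("staining percentages sum to more than 100")


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    tumor_depth: int
    normal_depth: int

    def __post_init__(self) -> None:
        if not 0 <= self.vaf <= 1:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.tumor_depth < 0 or self.normal_depth < 0:
            raise ValueError("negative sequencing depth")


def insm1_hscore(rec: IhcRecord) -> float:
    """INSM1 histochemical score in [0, 300].

    H = 1 x (% weak) + 2 x (% moderate) + 3 x (% strong).
    """
    return rec.pct_weak + 2.0 * rec.pct_moderate + 3.0 * rec.pct_strong


def filter_variants(records) -> list:
    """Keep variants with VAF > 0.10 and both depths > 50 (all strict).

    Order is preserved; malformed records are skipped with a warning.
    """
    kept = []
    n_bad = 0
    for rec in records:
        try:
            if not isinstance(rec, VariantRecord):
                rec = VariantRecord(**rec)
        except (TypeError, ValueError):
            n_bad += 1
            continue
        if rec.vaf > 0.10 and rec.tumor_depth > 50 and rec.normal_depth > 50:
            kept.append(rec)
    if n_bad:
        warnings.warn(f"{n_bad} malformed variant record(s) skipped")
    return kept


def read_variants(path) -> list:
    """Read a variant TSV; a VAF column in percent (values > 1) is
    auto-detected and rescaled with a warning."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV missing columns: {missing}")
    if (df["vaf"] > 1).any():
        warnings.warn("VAF column looks like percentages; dividing by 100")
        df["vaf"] = df["vaf"] / 100.0
    return [
        VariantRecord(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            vaf=float(r.vaf), tumor_depth=int(r.tumor_depth),
            normal_depth=int(r.normal_depth),
        )
        for r in df.itertuples()
    ]


def write_variants(records, path) -> None:
    pd.DataFrame([vars(r) for r in records], columns=VARIANT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )
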