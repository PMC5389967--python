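"""Cataloguing of MEI loci: complete/truncated classification and summaries.

A polymorphic insertion is "complete" (full-length) when its predicted length
reaches at least 90% of the maximum length for its family — LINEs truncate
from the 5' end during target-primed reverse transcription, so length is the
natural proxy for completeness.  Family maximum lengths come from a packaged
per-clade configuration (consensus full-length sizes), with the observed
per-family maximum as a fallback for unconfigured families.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import GenotypeTable, ValidationError


class Completeness(enum.Enum):
    COMPLETE = "complete"
    TRUNCATED = "truncated"


#: consensus full-length sizes (bp) by clade, upper end of each clade's range
CLADE_FULL_LENGTH_BP = {
    "R4": 3800,
    "RTE1": 3900,
    "RTEBovB": 3200,
    "CR1": 5800,
    "L2": 6300,
    "L1": 6800,
}


@dataclass
class FamilyLengthTable:
    """family -> maximum (full) element length in bp."""

    max_length: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for fam, ln in self.max_length.items():
            if ln <= 0:
                raise ValidationError(f"non-positive max length for {fam}")

    def get(self, family: str) -> int:
        try:
            return self.max_length[family]
        except KeyError:
            raise ValidationError(f"family {family!r} has no configured "
                                  "maximum length") from None

    @classmethod
    def from_clades(cls, family_clades: dict[str, str]) -> "FamilyLengthTable":
        """Assign each family its clade's consensus full length."""
        return cls({fam: CLADE_FULL_LENGTH_BP[clade]
                    for fam, clade in family_clades.items()})

    @classmethod
    def from_observed(cls, table: GenotypeTable) -> "FamilyLengthTable":
        """Fallback: per-family observed maximum predicted length."""
        df = table.sites.groupby("family")["length"].max()
        return cls({fam: int(ln) for fam, ln in df.items()})

    @classmethod
    def for_table(cls, table: GenotypeTable) -> "FamilyLengthTable":
        """Clade defaults where the clade is known, observed max elsewhere."""
        observed = cls.from_observed(table)
        out = dict(observed.max_length)
        for fam, clade in zip(table.sites["family"], table.sites["clade"]):
            if clade in CLADE_FULL_LENGTH_BP:
                out[fam] = CLADE_FULL_LENGTH_BP[clade]
        return cls(out)


def classify_complete(length_bp: int, family: str, lengths: FamilyLengthTable,
                      threshold_fraction: float = 0.9) -> Completeness:
    """COMPLETE iff length >= threshold_fraction x family maximum (inclusive)."""
    if length_bp >= threshold_fraction * lengths.get(family):
        return Completeness.COMPLETE
    return Completeness.TRUNCATED


def complete_mask(table: GenotypeTable, lengths: FamilyLengthTable,
                  threshold_fraction: float = 0.9) -> np.ndarray:
    thresholds = np.array([threshold_fraction * lengths.get(f)
                           for f in table.sites["family"]])
    return table.sites["length"].to_numpy() >= thresholds


def per_individual_counts(table: GenotypeTable, lengths: FamilyLengthTable,
                          threshold_fraction: float = 0.9) -> pd.DataFrame:
    """Per-sample totals of insertions present (dosage >= 1), all and complete.

    Returns a DataFrame with columns ``sample, population,
    n_insertions_present, n_full_length_present``.
    """
    full = complete_mask(table, lengths, threshold_fraction)
    present = table.dosage >= 1
    rows = []
    for j, s in enumerate(table.samples):
        rows.append({
            "sample": s,
            "population": (table.pop_map.assignments.get(s, "")
                           if table.pop_map else ""),
            "n_insertions_present": int(present[:, j].sum()),
            "n_full_length_present": int((present[:, j] & full).sum()),
        })
    return pd.DataFrame(rows)


def clade_summary(table: GenotypeTable, lengths: FamilyLengthTable,
                  by: str = "clade", threshold_fraction: float = 0.9
                  ) -> pd.DataFrame:
    """Counts of polymorphic loci per clade (or family), with full-length
    counts and fractions.  Empty groups yield a zero row, never a 0/0."""
    if by not in ("clade", "family"):
        raise ValidationError("by must be 'clade' or 'family'")
    full = complete_mask(table, lengths, threshold_fraction)
    df = pd.DataFrame({by: table.sites[by], "full": full})
    g = df.groupby(by, sort=True)["full"].agg(n_polymorphic="size",
                                              n_full_length="sum")
    g = g.reset_index()
    g["n_full_length"] = g["n_full_length"].astype(int)
    g["fraction_full_length"] = np.where(
        g["n_polymorphic"] > 0, g["n_full_length"] / g["n_polymorphic"], 0.0)
    return g


def length_histogram(table: GenotypeTable, bin_width_bp: int = 250
                     ) -> pd.DataFrame:
    """Per-clade histogram of predicted insertion lengths.

    Bins are half-open ``[lo, hi)`` of width ``bin_width_bp`` starting at 0.
    Returns tidy rows (clade, bin_lo, bin_hi, count); empty table -> empty
    frame.
    """
    if bin_width_bp < 1:
        raise ValidationError("bin width must be >= 1 bp")
    rows = []
    for clade, sub in table.sites.groupby("clade", sort=True):
        lens = sub["length"].to_numpy()
        if lens.size == 0:
            continue
        nbins = int(lens.max() // bin_width_bp) + 1
        counts = np.bincount((lens // bin_width_bp).astype(int),
                             minlength=nbins)
        for b, c in enumerate(counts):
            if c > 0:
                rows.append({"clade": clade, "bin_lo": b * bin_width_bp,
                             "bin_hi": (b + 1) * bin_width_bp,
                             "count": int(c)})
    return pd.DataFrame(rows, columns=["clade", "bin_lo", "bin_hi", "count"])
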