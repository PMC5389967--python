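"""Reading, filtering, thinning, merging and writing of SNP and MEI variant tables.

Two kinds of table flow through the pipeline:

* SNP tables: biallelic single-nucleotide sites with per-genotype depth (DP)
  and genotype quality (GQ) annotations, as produced by joint genotyping.
* MEI tables: mobile-element-insertion presence/absence loci in the style of
  MELT output, one callset per element family, with a predicted insertion
  length per locus.

All coordinates are 1-based point positions (VCF convention); an MEI locus is
represented by its insertion breakpoint.  Genotypes are stored as alternate /
insertion allele dosage per diploid sample (0, 1, 2; -1 encodes a missing
call, which only survives until filtering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: default population labels for the two-population analyses
POP1 = "FLORIDA"
POP2 = "GULF"


class ValidationError(ValueError):
    """Raised when an input table or argument violates a contract."""


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of samples to populations.

    Every sample appears exactly once.  ``populations`` preserves first-seen
    order; two-population statistics require exactly two non-empty groups.
    """

    assignments: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for pop in self.assignments.values():
            if pop not in seen:
                seen.append(pop)
        return seen

    def samples(self, population: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == population]
        if not out:
            raise ValidationError(f"unknown or empty population: {population!r}")
        return out

    @classmethod
    def read_tsv(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                         dtype=str, comment="#")
        dup = df["sample"].duplicated()
        if dup.any():
            raise ValidationError(f"duplicate samples in population map: "
                                  f"{sorted(df['sample'][dup])}")
        return cls(dict(zip(df["sample"], df["population"])))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.assignments.items():
                fh.write(f"{s}\t{p}\n")


@dataclass
class GenotypeTable:
    """Ordered collection of variant sites sharing one sample set.

    ``sites`` is a DataFrame with columns ``chrom, pos, ref, alt, qual`` and,
    for MEI tables, additionally ``family, clade, length, pass_quality``.
    ``dosage`` is an ``(n_sites, n_samples)`` int16 matrix of alternate-allele
    dosages.  SNP tables carry parallel ``depth`` and ``gq`` matrices; a value
    of -1 marks a genotype whose annotation was absent in the source VCF.
    Records are kept sorted by (chrom, pos).
    """

    kind: str                      # "snp" | "mei"
    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    pop_map: PopulationMap | None = None

    def __post_init__(self):
        if self.kind not in ("snp", "mei"):
            raise ValidationError(f"kind must be 'snp' or 'mei', got {self.kind!r}")
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, population: str | None = None) -> np.ndarray:
        """Column indices of the samples of one population (or all)."""
        if population is None:
            return np.arange(self.n_samples)
        if self.pop_map is None:
            raise ValidationError("table has no population map attached")
        wanted = set(self.pop_map.samples(population))
        idx = np.array([i for i, s in enumerate(self.samples) if s in wanted])
        if idx.size == 0:
            raise ValidationError(f"no table samples belong to {population!r}")
        return idx

    def take(self, row_mask_or_idx) -> "GenotypeTable":
        """Row subset preserving order; returns a new table."""
        idx = np.asarray(row_mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[idx],
            depth=None if self.depth is None else self.depth[idx],
            gq=None if self.gq is None else self.gq[idx],
        )

    def sorted(self) -> "GenotypeTable":
        order = np.lexsort((self.sites["pos"].to_numpy(),
                            self.sites["chrom"].to_numpy()))
        return self.take(order)

    def allele_counts(self, population: str | None = None) -> tuple[np.ndarray, int]:
        """(derived/alternate allele count per site, number of chromosomes)."""
        idx = self.sample_indices(population)
        d = self.dosage[:, idx]
        if (d < 0).any():
            raise ValidationError("missing genotypes present; filter first")
        return d.sum(axis=1), 2 * idx.size


# ---------------------------------------------------------------------------
# VCF reading (cyvcf2) and writing
# ---------------------------------------------------------------------------

_VCF_HEADER = "\t".join(
    ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"])


def read_vcf(path, kind: str = "snp", pop_map: PopulationMap | None = None,
             default_clade: str = "", default_family: str = "") -> GenotypeTable:
    """Read a VCF 4.2 file into a :class:`GenotypeTable`.

    For ``kind="mei"`` the insertion length is taken from INFO/SVLEN when
    present, else from the MELT-style INFO/MEINFO span (start/end fields);
    family comes from INFO/FAMILY, else the first MEINFO field, else
    ``default_family``; clade from INFO/CLADE else ``default_clade``.  A
    record whose FILTER column is neither PASS nor '.' is kept but marked
    ``pass_quality=False`` so downstream merging can drop it.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages, depths, gqs = [], [], [], []
    for var in vcf:
        gt = np.asarray(var.genotype.array())[:, :2]
        dos = np.where((gt < 0).any(axis=1), MISSING, (gt > 0).sum(axis=1))
        row = {
            "chrom": var.CHROM,
            "pos": var.POS,
            "ref": var.REF,
            "alt": var.ALT[0] if var.ALT else ".",
            "qual": var.QUAL if var.QUAL is not None else np.nan,
        }
        if kind == "mei":
            row["length"] = _mei_length(var)
            row["family"] = _info_str(var, "FAMILY") or _meinfo_field(var, 0) \
                or default_family
            row["clade"] = _info_str(var, "CLADE") or default_clade
            row["pass_quality"] = var.FILTER is None or var.FILTER == "PASS"
        rows.append(row)
        dosages.append(dos)
        if kind == "snp":
            depths.append(_format_int(var, "DP", len(samples)))
            gqs.append(_format_int(var, "GQ", len(samples)))
    sites = pd.DataFrame(rows) if rows else _empty_sites(kind)
    table = GenotypeTable(
        kind=kind,
        samples=samples,
        sites=sites,
        dosage=(np.array(dosages, dtype=np.int16)
                if rows else np.zeros((0, len(samples)), dtype=np.int16)),
        depth=np.array(depths, dtype=np.int32) if depths else
              (np.zeros((0, len(samples)), np.int32) if kind == "snp" else None),
        gq=np.array(gqs, dtype=np.int32) if gqs else
           (np.zeros((0, len(samples)), np.int32) if kind == "snp" else None),
        pop_map=pop_map,
    )
    return table.sorted()


def _empty_sites(kind: str) -> pd.DataFrame:
    cols = ["chrom", "pos", "ref", "alt", "qual"]
    if kind == "mei":
        cols += ["length", "family", "clade", "pass_quality"]
    return pd.DataFrame(columns=cols)


def _info_str(var, key):
    val = var.INFO.get(key)
    return str(val) if val is not None else None


def _meinfo_field(var, i):
    raw = var.INFO.get("MEINFO")
    if raw is None:
        return None
    parts = str(raw).split(",")
    return parts[i] if i < len(parts) else None


def _format_int(var, key: str, n_samples: int) -> np.ndarray:
    """Per-sample integer FORMAT field; -1 where absent or missing."""
    arr = var.format(key)
    if arr is None:
        return np.full(n_samples, MISSING, dtype=np.int32)
    arr = np.asarray(arr).reshape(n_samples, -1)[:, 0].astype(np.int64)
    # cyvcf2 encodes missing FORMAT integers as large negative sentinels
    arr = np.where(arr < 0, MISSING, arr)
    return arr.astype(np.int32)


def _mei_length(var) -> int:
    svlen = var.INFO.get("SVLEN")
    if svlen is not None:
        try:
            return abs(int(svlen))
        except (TypeError, ValueError):
            return abs(int(np.atleast_1d(svlen)[0]))
    raw = var.INFO.get("MEINFO")
    if raw is not None:
        parts = str(raw).split(",")
        if len(parts) >= 3:
            return abs(int(parts[2]) - int(parts[1]))
    raise ValidationError(f"no insertion length (SVLEN/MEINFO) at "
                          f"{var.CHROM}:{var.POS}")


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a GenotypeTable as uncompressed VCF 4.2.

    MEI tables emit both SVLEN and a MELT-style MEINFO so either dialect can
    be read back; dosage d is rendered as an unphased genotype with d copies
    of the alternate allele.  SNP tables emit GT:DP:GQ.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if table.kind == "snp":
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        else:
            fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Insertion length">\n')
            fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
            fh.write('##INFO=<ID=MEINFO,Number=4,Type=String,Description="Mobile element info: NAME,START,END,POLARITY">\n')
            fh.write('##INFO=<ID=FAMILY,Number=1,Type=String,Description="Element family">\n')
            fh.write('##INFO=<ID=CLADE,Number=1,Type=String,Description="Element clade">\n')
        for chrom in pd.unique(table.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(_VCF_HEADER + "\t" + "\t".join(table.samples) + "\n")
        fmt = "GT:DP:GQ" if table.kind == "snp" else "GT"
        for i, row in enumerate(table.sites.itertuples(index=False)):
            qual = "." if pd.isna(row.qual) else f"{row.qual:g}"
            if table.kind == "mei":
                length = int(row.length)
                info = (f"SVTYPE=INS;SVLEN={length};"
                        f"MEINFO={row.family},1,{1 + length},+;"
                        f"FAMILY={row.family};CLADE={row.clade}")
                filt = "PASS" if row.pass_quality else "lc"
            else:
                info, filt = ".", "PASS"
            cells = []
            for j in range(table.n_samples):
                d = table.dosage[i, j]
                gt = "./." if d < 0 else ["0/0", "0/1", "1/1"][d]
                if table.kind == "snp":
                    dp = table.depth[i, j] if table.depth is not None else MISSING
                    gq = table.gq[i, j] if table.gq is not None else MISSING
                    cells.append(f"{gt}:{dp if dp >= 0 else '.'}:{gq if gq >= 0 else '.'}")
                else:
                    cells.append(gt)
            fh.write("\t".join([str(row.chrom), str(row.pos), ".", str(row.ref),
                                str(row.alt), qual, filt, info, fmt] + cells) + "\n")


def write_tsv(table: GenotypeTable, path) -> None:
    """Flat TSV export: site columns then one dosage column per sample."""
    df = table.sites.copy()
    for j, s in enumerate(table.samples):
        df[s] = table.dosage[:, j]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering / thinning / merging
# ---------------------------------------------------------------------------

def filter_snps(table: GenotypeTable, min_dp: int = 6, min_gq: int = 20,
                min_q: float = 20.0, min_fraction_called: float = 1.0,
                biallelic_only: bool = True,
                remove_indels: bool = True) -> GenotypeTable:
    """Site-wise SNP quality filtering.

    A site is retained only if: its QUAL is at least ``min_q``; it is a true
    SNP (single-base REF and ALT) when ``remove_indels``; it is biallelic when
    ``biallelic_only``; and, after masking genotypes with depth below
    ``min_dp`` or genotype quality below ``min_gq``, the fraction of called
    genotypes is at least ``min_fraction_called``.  The default of 1.0 keeps
    only sites genotyped in every sample after quality masking, so a single
    failing genotype fails the whole site.  Sites lacking depth/quality
    annotations are rejected and logged rather than aborting the run.
    """
    if table.kind != "snp":
        raise ValidationError("filter_snps expects a SNP table")
    if not 0.0 <= min_fraction_called <= 1.0:
        raise ValidationError("min_fraction_called must be in [0, 1]")
    n = table.n_samples
    keep = np.ones(table.n_sites, dtype=bool)

    qual = table.sites["qual"].to_numpy(dtype=float)
    keep &= ~np.isnan(qual) & (qual >= min_q)

    ref = table.sites["ref"].astype(str)
    alt = table.sites["alt"].astype(str)
    if remove_indels:
        keep &= (ref.str.len() == 1).to_numpy() & (alt.str.len() == 1).to_numpy()
    if biallelic_only:
        # multi-allelic records carry comma-joined ALT strings
        keep &= ~alt.str.contains(",").to_numpy()

    if table.depth is None or table.gq is None:
        if min_dp > 0 or min_gq > 0:
            logger.warning("table lacks DP/GQ matrices; rejecting all sites")
            return table.take(np.zeros(table.n_sites, dtype=bool))
        called = table.dosage >= 0
    else:
        annotated = (table.depth >= 0) & (table.gq >= 0)
        bad_annot = ~annotated.all(axis=1) & keep
        if bad_annot.any() and (min_dp > 0 or min_gq > 0):
            logger.warning("rejecting %d sites with missing DP/GQ annotations",
                           int(bad_annot.sum()))
            keep &= annotated.all(axis=1)
        called = ((table.dosage >= 0) & (table.depth >= min_dp)
                  & (table.gq >= min_gq))
    keep &= called.sum(axis=1) >= min_fraction_called * n

    out = table.take(keep)
    logger.info("filter_snps: %d of %d sites retained", out.n_sites, table.n_sites)
    return out


def thin_snps(table: GenotypeTable, step: int) -> GenotypeTable:
    """Keep every ``step``-th site (ordinals 1, 1+step, ...) in sorted order.

    Thinning is genome-wide over the sorted table; it limits linkage between
    retained markers after dense genotyping.
    """
    if step < 1:
        raise ValidationError(f"step must be >= 1, got {step}")
    return table.take(np.arange(0, table.n_sites, step))


def merge_mei_callsets(callsets: list[GenotypeTable],
                       require_full_coverage: bool = True) -> GenotypeTable:
    """Union of per-family MEI callsets over a shared sample set.

    With ``require_full_coverage`` (the default), loci with any missing
    genotype or a failing quality flag are removed, mirroring the combine step
    that keeps only loci covered and confidently called in all samples.
    """
    if not callsets:
        raise ValidationError("no callsets to merge")
    ref_samples = callsets[0].samples
    for k, cs in enumerate(callsets):
        if cs.kind != "mei":
            raise ValidationError(f"callset {k} is not an MEI table")
        if cs.samples != ref_samples:
            raise ValidationError(
                f"callset {k} has sample set {cs.samples}, expected {ref_samples}")
    merged = replace(
        callsets[0],
        sites=pd.concat([c.sites for c in callsets], ignore_index=True),
        dosage=np.concatenate([c.dosage for c in callsets], axis=0),
        depth=None, gq=None,
    )
    if require_full_coverage:
        ok = (merged.dosage >= 0).all(axis=1)
        ok &= merged.sites["pass_quality"].to_numpy(dtype=bool)
        merged = merged.take(ok)
    return merged.sorted()


def dedup_nearby(table: GenotypeTable, window_bp: int = 50) -> GenotypeTable:
    """Collapse clusters of nearby MEI calls to the longest element.

    Clusters are built by single-linkage chaining: on each chromosome,
    consecutive sorted records within ``window_bp`` of each other join one
    cluster.  Within a cluster only the record of maximal predicted length
    survives; length ties go to the lowest position.
    """
    if table.kind != "mei":
        raise ValidationError("dedup_nearby expects an MEI table")
    t = table.sorted()
    if t.n_sites == 0:
        return t
    chrom = t.sites["chrom"].to_numpy()
    pos = t.sites["pos"].to_numpy()
    length = t.sites["length"].to_numpy()
    new_cluster = np.ones(t.n_sites, dtype=bool)
    new_cluster[1:] = (chrom[1:] != chrom[:-1]) | (pos[1:] - pos[:-1] > window_bp)
    cluster_id = np.cumsum(new_cluster) - 1
    keep = []
    for cid in np.unique(cluster_id):
        members = np.flatnonzero(cluster_id == cid)
        best = members[np.argmax(length[members])]  # argmax -> first = lowest pos on tie
        keep.append(best)
    return t.take(np.sort(np.array(keep)))
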