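"""Quantification of 3'-end sequencing reads at annotated polyA sites.

3'-targeted protocols (QuantSeq-style) produce one read cluster per transcript
3' end. Each annotated cleavage site is extended into a strand-aware window
(200 nt upstream, 20 nt downstream by default), overlapping same-strand
windows are merged, and reads -- narrowed to their 3'-most nucleotide -- are
counted per window and aggregated per gene. A second species mixed in at a
known cell ratio before lysis serves as a spike-in: the fly/human read ratio,
scaled by the mixing ratio, is constant across conditions unless absolute RNA
levels change.

All coordinates are 0-based half-open. The cleavage nucleotide itself is
inside the window, so an unmerged window has length ext5 + ext3 + 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PasSite:
    """A single annotated cleavage/polyadenylation position."""

    chrom: str
    strand: str
    cleavage_pos: int
    gene_id: str
    species: str = "human"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.cleavage_pos < 0:
            raise ValueError("cleavage_pos must be >= 0")


@dataclass
class PasInterval:
    """An extended (and possibly merged) polyA-site window, half-open."""

    chrom: str
    strand: str
    start: int
    end: int
    gene_ids: frozenset[str]
    species: str = "human"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("interval must satisfy start < end")


@dataclass
class PasCountTable:
    """Counts per interval and per gene for one or more samples.

    ``interval_counts``: DataFrame indexed by interval ordinal with columns
    chrom/strand/start/end/species plus one column per sample.
    ``gene_counts``: genes x samples DataFrame (a read in an interval shared
    by several genes contributes to each of them).
    ``species_totals``: species x samples totals of PAS-associated reads.
    ``unassigned``: per-sample count of reads overlapping no interval.
    """

    interval_counts: pd.DataFrame
    gene_counts: pd.DataFrame
    species_totals: pd.DataFrame
    unassigned: pd.Series
    gene_species: pd.Series = field(default=None)


def extend_and_merge(
    sites: list[PasSite], ext3: int = 20, ext5: int = 200
) -> list[PasInterval]:
    """Extend each cleavage site into a strand-aware window and merge overlaps.

    A + strand site at p becomes [p-ext5, p+ext3+1); a - strand site becomes
    [p-ext3, p+ext5+1). Windows overlapping on the same chromosome and strand
    (within a species) are combined, unioning their gene associations. Starts
    are clipped at zero.
    """
    if ext3 < 0 or ext5 < 0:
        raise ValueError("extensions must be non-negative")
    windows = []
    for s in sites:
        if s.strand == "+":
            start, end = s.cleavage_pos - ext5, s.cleavage_pos + ext3 + 1
        else:
            start, end = s.cleavage_pos - ext3, s.cleavage_pos + ext5 + 1
        windows.append((s.species, s.chrom, s.strand, max(0, start), end, s.gene_id))

    windows.sort(key=lambda w: (w[0], w[1], w[2], w[3], w[4]))
    merged: list[PasInterval] = []
    for species, chrom, strand, start, end, gene in windows:
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.species == species
            and last.chrom == chrom
            and last.strand == strand
            and start < last.end  # half-open: touching windows do not overlap
        ):
            last.end = max(last.end, end)
            last.gene_ids = last.gene_ids | {gene}
        else:
            merged.append(
                PasInterval(chrom, strand, start, end, frozenset({gene}), species)
            )
    return merged


def count_read_ends(
    reads: pd.DataFrame,
    intervals: list[PasInterval],
    whitelist: set[str] | None = None,
    require_strand_match: bool = True,
    sample_col: str = "sample",
) -> PasCountTable:
    """Count read 3'-end positions falling inside extended PAS windows.

    ``reads`` needs columns chrom, strand, pos_3prime and optionally a sample
    column (absent -> one sample named 'sample_1'). Each read is counted at
    most once (merged windows are disjoint). Gene counts aggregate the
    windows associated with each gene; genes outside ``whitelist`` (when
    given) are dropped from the gene table but still count toward species
    totals, mirroring exclusion of genes absent from the reference gene set.
    """
    reads = reads.copy()
    if sample_col not in reads.columns:
        reads[sample_col] = "sample_1"
    samples = sorted(reads[sample_col].unique())

    # disjoint sorted windows per (chrom, strand) -> searchsorted assignment
    meta = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "strand": [iv.strand for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "species": [iv.species for iv in intervals],
        }
    )
    by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for key, grp in meta.groupby(["chrom", "strand"], sort=False):
        grp = grp.sort_values("start")
        by_key[key] = (grp["start"].to_numpy(), grp["end"].to_numpy(), grp.index.to_numpy())

    counts = np.zeros((len(intervals), len(samples)), dtype=np.int64)
    unassigned = pd.Series(0, index=samples, dtype=np.int64)
    sample_idx = {s: j for j, s in enumerate(samples)}

    strands = ("+", "-")
    for (chrom, strand, samp), grp in reads.groupby(["chrom", "strand", sample_col], sort=False):
        if strand not in strands:
            raise ValueError(f"invalid strand {strand!r} in reads")
        pos = grp["pos_3prime"].to_numpy()
        j = sample_idx[samp]
        if require_strand_match:
            keys = [(chrom, strand)]
        else:
            keys = [(chrom, s) for s in strands]
        assigned = np.zeros(pos.size, dtype=bool)
        for key in keys:
            if key not in by_key:
                continue
            starts, ends, idx = by_key[key]
            k = np.searchsorted(starts, pos, side="right") - 1
            ok = (k >= 0) & ~assigned
            ok[ok] &= pos[ok] < ends[k[ok]]
            np.add.at(counts[:, j], idx[k[ok]], 1)
            assigned |= ok
        unassigned[samp] += int((~assigned).sum())

    interval_counts = pd.concat(
        [meta, pd.DataFrame(counts, columns=samples)], axis=1
    )
    species_totals = interval_counts.groupby("species")[samples].sum()

    gene_rows: dict[str, np.ndarray] = {}
    gene_species: dict[str, str] = {}
    for i, iv in enumerate(intervals):
        for g in iv.gene_ids:
            if whitelist is not None and g not in whitelist:
                continue
            gene_rows[g] = gene_rows.get(g, np.zeros(len(samples), dtype=np.int64)) + counts[i]
            gene_species[g] = iv.species
    gene_counts = pd.DataFrame.from_dict(gene_rows, orient="index", columns=samples)
    gene_counts = gene_counts.sort_index()

    return PasCountTable(
        interval_counts=interval_counts,
        gene_counts=gene_counts,
        species_totals=species_totals,
        unassigned=unassigned,
        gene_species=pd.Series(gene_species).reindex(gene_counts.index),
    )


def spike_in_ratio(
    table: PasCountTable,
    mixing_ratio: float,
    fly: str = "fly",
    human: str = "human",
) -> pd.Series:
    """Fly/human PAS-read ratio per sample, scaled by the known cell mixing ratio.

    With equal capture efficiency the scaled ratio is 1 regardless of which
    mixing ratio (e.g. 1:4 -> 0.25 or 5:4 -> 1.25) was used, so departures
    across conditions indicate absolute RNA-level changes in the human cells.
    """
    if mixing_ratio <= 0:
        raise ValueError("mixing_ratio must be positive")
    for sp in (fly, human):
        if sp not in table.species_totals.index:
            raise ValueError(f"species {sp!r} absent from count table")
    human_tot = table.species_totals.loc[human].astype(float)
    if (human_tot == 0).any():
        raise ValueError("zero human PAS reads in at least one sample")
    return (table.species_totals.loc[fly] / human_tot) / mixing_ratio


def spike_in_anova(scaled_ratios: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """One-way ANOVA of scaled spike-in ratios across condition groups."""
    vals = [scaled_ratios[groups == g].to_numpy(dtype=float) for g in groups.unique()]
    if len(vals) < 2:
        raise ValueError("need at least two condition groups")
    f, p = stats.f_oneway(*vals)
    return float(f), float(p)


def rpm(table: PasCountTable, species: str | None = None) -> pd.DataFrame:
    """Per-gene reads-per-million.

    Each sample's gene counts are divided by that sample's total
    PAS-associated reads (optionally restricted to one species) and scaled by
    1e6. Per-gene RPM is the sum over the gene's windows, which the gene
    table already aggregates.
    """
    gene_counts = table.gene_counts
    if species is not None:
        keep = table.gene_species == species
        gene_counts = gene_counts.loc[keep[keep].index]
        totals = table.species_totals.loc[species].astype(float)
    else:
        totals = table.species_totals.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("sample with zero PAS-associated reads")
    return gene_counts / totals * 1e6


def rpm_condition_means(rpm_table: pd.DataFrame, condition: pd.Series) -> pd.DataFrame:
    """Average RPM across replicate samples of each condition."""
    return rpm_table.T.groupby(condition).mean().T
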