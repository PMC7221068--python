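"""Chromatin occupancy and affinity analysis.

Occupancy: replicate consensus per condition, then a parent-vs-hybrid peak
partition (a peak is consensus if it shares >=1 base with any peak of the
other background, else background-specific) and a rank-sum comparison of peak
scores between the partitions — background-specific peaks scoring low is a
hint they are weak calls.

Affinity: promoter regions are the strand-aware upstream intervals of each
gene, up to 1 kb, truncated at the nearest gene body or chromosome border;
per-promoter coverage sums are tested for differential accessibility between
the two sub-genomes with the NB engine, controlling for promoter length via
allele-length-style factors; calls use |l2fc| > 1 and padj < 0.01.

Coordinates: BED/narrowPeak/bedGraph 0-based half-open; GTF annotations
1-based inclusive, converted here. All internal arithmetic is half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from hybridshock import degene
from hybridshock.intervals import PeakSet, merge_clusters

TRUNCATION_REASONS = ("full_1kb", "neighbor_gene", "chromosome_border")


# ------------------------------------------------------------------ masking
def mask_regions(sequences: dict[str, str], regions: pd.DataFrame) -> dict[str, str]:
    """Replace the bases of BED regions (0-based half-open) with ``N``."""
    out = dict(sequences)
    for row in regions.itertuples(index=False):
        seq = out.get(row.chrom)
        if seq is None:
            raise KeyError(f"chromosome {row.chrom!r} absent from genome")
        if row.start < 0 or row.end > len(seq) or row.start >= row.end:
            raise ValueError(
                f"region {row.chrom}:{row.start}-{row.end} out of bounds")
        out[row.chrom] = seq[:row.start] + "N" * (row.end - row.start) + seq[row.end:]
    return out


# ---------------------------------------------------------------- occupancy
def replicate_consensus(replicates: list[PeakSet], min_reps: int = 2,
                        label: str = "consensus") -> PeakSet:
    """Union peaks supported by >= ``min_reps`` replicates.

    Overlapping peaks (>=1 shared base) across replicates are clustered; a
    cluster supported by enough distinct replicates becomes one consensus peak
    spanning the union of its members, scored with their mean score.
    """
    if min_reps > len(replicates):
        raise ValueError("min_reps exceeds the number of replicate sets")
    pooled = pd.concat(
        [r.df.assign(_rep=i) for i, r in enumerate(replicates)],
        ignore_index=True)
    rows = []
    for j, cluster in enumerate(merge_clusters(pooled)):
        if cluster["_rep"].nunique() >= min_reps:
            rows.append((cluster["chrom"].iloc[0],
                         int(cluster["start"].min()), int(cluster["end"].max()),
                         f"{label}_{j + 1:05d}", float(cluster["score"].mean())))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                               "name", "score"]), label=label)


def partition_peaksets(parent: PeakSet, hybrid: PeakSet) -> dict:
    """Partition two peak sets into consensus and background-specific parts.

    Reported from each side, so ``|consensus_from_parent| + |parent_specific|
    == |parent|`` and symmetrically for the hybrid.
    """
    if len(parent) and len(hybrid):
        shared_chroms = set(parent.df["chrom"]) | set(hybrid.df["chrom"])
        if not (set(parent.df["chrom"]) & set(hybrid.df["chrom"])) and shared_chroms:
            raise ValueError("peak sets share no chromosome namespace")
    p_mask = parent.overlaps_mask(hybrid)
    h_mask = hybrid.overlaps_mask(parent)
    return {
        "consensus_from_parent": parent.subset(p_mask, "consensus_from_parent"),
        "parent_specific": parent.subset(~p_mask, "parent_specific"),
        "consensus_from_hybrid": hybrid.subset(h_mask, "consensus_from_hybrid"),
        "hybrid_specific": hybrid.subset(~h_mask, "hybrid_specific"),
        "counts": {
            "parent": len(parent), "hybrid": len(hybrid),
            "consensus_from_parent": int(p_mask.sum()),
            "parent_specific": int((~p_mask).sum()),
            "consensus_from_hybrid": int(h_mask.sum()),
            "hybrid_specific": int((~h_mask).sum()),
        },
    }


def score_comparison(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between peak-score groups.

    Exact p-values for small tie-free samples, otherwise the normal
    approximation with tie and continuity corrections.
    """
    names = list(groups)
    for name in names:
        if len(np.asarray(groups[name])) == 0:
            raise ValueError(f"score group {name!r} is empty")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = stats.mannwhitneyu(groups[a], groups[b],
                                     alternative="two-sided", method="auto")
            rows.append((a, b, float(res.statistic), float(res.pvalue),
                         float(np.median(groups[a])), float(np.median(groups[b]))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic",
                                       "p", "median_a", "median_b"])


# ---------------------------------------------------------------- promoters
def define_promoters(annotations: pd.DataFrame, chrom_lengths: dict[str, int],
                     max_len: int = 1000) -> pd.DataFrame:
    """Strand-aware upstream promoter intervals, 0-based half-open.

    Each promoter abuts its gene's 5' end and extends upstream until
    ``max_len``, the nearest annotated gene body, or the chromosome border —
    whichever comes first. Zero-length promoters (abutting genes) are emitted
    with length 0 so callers can exclude them explicitly.
    """
    rows = []
    for chrom, sub in annotations.groupby("chrom"):
        clen = chrom_lengths[chrom]
        bodies = np.array(sorted(
            (int(s) - 1, int(e)) for s, e in zip(sub["start"], sub["end"])))
        b_starts, b_ends = bodies[:, 0], bodies[:, 1]
        for row in sub.itertuples(index=False):
            g0, g1 = int(row.start) - 1, int(row.end)  # half-open body
            if row.strand == "+":
                limit = g0 - max_len
                prev_ends = b_ends[b_ends <= g0]
                neighbor = int(prev_ends.max()) if len(prev_ends) else None
                start = max(limit, 0, neighbor if neighbor is not None else 0)
                end = g0
                if start == limit and start >= 0:
                    reason = "full_1kb"
                elif neighbor is not None and start == neighbor and neighbor > max(limit, 0):
                    reason = "neighbor_gene"
                elif start == 0 and limit < 0 and (neighbor is None or neighbor <= 0):
                    reason = "chromosome_border"
                else:
                    reason = "neighbor_gene"
            else:
                limit = g1 + max_len
                next_starts = b_starts[b_starts >= g1]
                neighbor = int(next_starts.min()) if len(next_starts) else None
                end = min(limit, clen, neighbor if neighbor is not None else clen)
                start = g1
                if end == limit and end <= clen:
                    reason = "full_1kb"
                elif neighbor is not None and end == neighbor and neighbor < min(limit, clen):
                    reason = "neighbor_gene"
                elif end == clen and limit > clen and (neighbor is None or neighbor >= clen):
                    reason = "chromosome_border"
                else:
                    reason = "neighbor_gene"
            rows.append((row.gene_id, chrom, row.strand, start, end,
                         end - start, reason))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start",
                                       "end", "length", "reason"])


def promoter_counts(coverage: pd.DataFrame, promoters: pd.DataFrame) -> pd.Series:
    """Summed per-base coverage over each promoter (a read-count proxy).

    ``coverage`` is bedGraph-shaped (chrom, start, end, value), half-open.
    Zero-length promoters get 0. Raises if a non-trivial promoter's chromosome
    has no coverage rows at all.
    """
    cov_by_chrom = {c: s.sort_values("start") for c, s in coverage.groupby("chrom")}
    out = {}
    for row in promoters.itertuples(index=False):
        if row.length == 0:
            out[row.gene_id] = 0.0
            continue
        sub = cov_by_chrom.get(row.chrom)
        if sub is None:
            raise KeyError(f"no coverage for chromosome {row.chrom!r}")
        s = np.maximum(sub["start"].to_numpy(), row.start)
        e = np.minimum(sub["end"].to_numpy(), row.end)
        ov = np.maximum(e - s, 0)
        out[row.gene_id] = float((ov * sub["value"].to_numpy()).sum())
    return pd.Series(out, name="coverage")


# ----------------------------------------------------------------- affinity
def differential_accessibility(counts: pd.DataFrame, lengths: pd.DataFrame,
                               groups: pd.Series, numerator: str = "B",
                               denominator: str = "A",
                               l2fc_min: float = 1.0, padj_max: float = 0.01,
                               shrink: float = 0.0) -> dict:
    """Promoter-level differential accessibility between sub-genomes.

    ``counts``: regions x samples (integer coverage proxies); ``lengths``:
    matching promoter lengths so region-length differences are controlled via
    allele-length-style normalization factors.
    """
    if not counts.index.equals(lengths.index):
        raise ValueError("counts and lengths must share the region index")
    res = degene.run_de(counts.round().astype(int), groups,
                        numerator=numerator, denominator=denominator,
                        mode="allele_length_only", lengths=lengths,
                        shrink=shrink, name="differential_accessibility")
    de = degene.call_de(res, l2fc_min=l2fc_min, padj_max=padj_max)
    return {"result": res, "de": de}


# -------------------------------------------------------------- integration
def assign_peaks_to_genes(peaks: PeakSet, annotations: pd.DataFrame,
                          promoters: pd.DataFrame,
                          max_dist: int = 1000) -> pd.DataFrame:
    """Link peaks to genes whose promoter they overlap within 1 kb.

    For each peak and each strand, the nearest gene whose body lies within
    ``max_dist`` of the peak and whose promoter shares >=1 base with the peak.
    Unlinked peaks are reported with ``gene_id`` NA.
    """
    prom = promoters.set_index("gene_id")
    rows = []
    ann_by_chrom = {c: s for c, s in annotations.groupby("chrom")}
    for peak in peaks.df.itertuples(index=False):
        sub = ann_by_chrom.get(peak.chrom)
        linked = []
        if sub is not None:
            for gene in sub.itertuples(index=False):
                g0, g1 = int(gene.start) - 1, int(gene.end)
                dist = max(g0 - peak.end, peak.start - g1, 0)
                if dist > max_dist:
                    continue
                pr = prom.loc[gene.gene_id]
                if pr["length"] == 0:
                    continue
                if min(pr["end"], peak.end) - max(pr["start"], peak.start) >= 1:
                    linked.append((gene.strand, dist, gene.gene_id))
        if not linked:
            rows.append((peak.name, peak.chrom, peak.start, peak.end, None, None))
        else:
            for strand in ("+", "-"):
                cands = sorted(x for x in linked if x[0] == strand)
                if cands:
                    _, dist, gid = min(cands, key=lambda x: x[1])
                    rows.append((peak.name, peak.chrom, peak.start, peak.end,
                                 gid, strand))
    return pd.DataFrame(rows, columns=["peak", "chrom", "start", "end",
                                       "gene_id", "gene_strand"])


def integrate_expression(links: pd.DataFrame, de_result: pd.DataFrame,
                         direction_map: dict[str, str] | None = None) -> dict:
    """Join peak->gene links with DE calls and summarize concordance.

    ``de_result`` is a called-DE frame (index = gene/pair id, ``direction``).
    ``direction_map`` optionally maps each link's expected direction (e.g. a
    hybrid-specific peak predicts "up" in the hybrid); without it, any DE
    status counts as a hit and concordance is direction-blind.
    """
    linked = links[links["gene_id"].notna()].copy()
    linked["de_direction"] = linked["gene_id"].map(
        de_result["direction"] if len(de_result) else pd.Series(dtype=object))
    same = opposite = no_de = 0
    for row in linked.itertuples(index=False):
        if pd.isna(row.de_direction):
            no_de += 1
        elif direction_map is None:
            same += 1
        else:
            expected = direction_map.get(row.peak)
            if expected is None or expected == row.de_direction:
                same += 1
            else:
                opposite += 1
    return {"table": linked,
            "concordance": {"same_direction": same, "opposite": opposite,
                            "no_de": no_de}}
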