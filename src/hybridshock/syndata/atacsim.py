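"""ATAC-style fixtures: replicate peak sets with shared/background-specific
structure, and matching coverage tracks.

The simulator emulates the occupancy comparison between a parental genome and
the corresponding sub-genome of the hybrid: each background carries ``n_peaks``
open-chromatin peaks centered on promoter-like template intervals; a
``shared_fraction`` of each background's peaks sit on templates common to both
backgrounds, the rest are background-specific. Background-specific peaks
receive lower scores on average (specific calls tend to be weak), replicate
sets are jittered copies of the background truth, and the coverage track is
the box-sum implied by the true peaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hybridshock.intervals import PeakSet, coverage_from_peaks

BACKGROUNDS = ("parent", "hybrid")


def random_promoter_grid(n: int, width: int = 500, spacing: int = 2000,
                         chrom_len: int = 2_000_000, seed: int = 0) -> pd.DataFrame:
    """Promoter-like template intervals tiled over as many chromosomes as needed.

    A cheap stand-in for real promoter maps when a fixture needs more
    templates than a small synthetic genome provides.
    """
    rng = np.random.default_rng(seed)
    per_chrom = max(1, chrom_len // spacing - 1)
    rows = []
    for i in range(n):
        chrom = f"chr{i // per_chrom + 1}"
        base = (i % per_chrom) * spacing + spacing // 2
        start = base + int(rng.integers(0, max(1, spacing - width - 200)))
        rows.append((chrom, start, start + width, f"tmpl_{i + 1:05d}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def simulate_atac(
    promoters: pd.DataFrame,
    shared_fraction: float = 0.88,
    n_reps: int = 3,
    seed: int = 0,
    n_peaks: int | None = None,
    peak_width: int = 300,
    jitter: int = 20,
    shared_score: tuple[float, float] = (600.0, 120.0),
    specific_score: tuple[float, float] = (300.0, 90.0),
) -> tuple[dict[str, list[PeakSet]], dict[str, pd.DataFrame]]:
    """Simulate replicate ATAC peak sets and coverage for two backgrounds.

    Parameters
    ----------
    promoters
        Template intervals (columns ``chrom, start, end``; 0-based half-open).
        Peaks are centered on a subset of them. Each background draws
        ``n_peaks`` peaks; templates needed = ``shared + 2 * specific``.
    shared_fraction
        Fraction of each background's peaks present in both backgrounds, so
        the consensus/specific partition recovers it directly.
    jitter
        Max absolute coordinate noise per replicate (0 = identical replicates).

    Returns
    -------
    peaks : dict background -> list of replicate PeakSets
    coverage : dict background -> bedGraph-shaped DataFrame
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    templates = promoters.reset_index(drop=True)
    if n_peaks is None:
        n_peaks = int(len(templates) // (1 + (1 - shared_fraction)))
    n_shared = int(round(shared_fraction * n_peaks))
    n_specific = n_peaks - n_shared
    needed = n_shared + 2 * n_specific
    if needed > len(templates):
        raise ValueError(
            f"need {needed} template intervals, have {len(templates)}")

    order = rng.permutation(len(templates))[:needed]
    shared_idx = order[:n_shared]
    spec_idx = {"parent": order[n_shared:n_shared + n_specific],
                "hybrid": order[n_shared + n_specific:needed]}

    def truth_peaks(background: str) -> pd.DataFrame:
        rows = []
        for kind, idx in (("shared", shared_idx), ("specific", spec_idx[background])):
            mu, sd = shared_score if kind == "shared" else specific_score
            centers = ((templates.loc[idx, "start"] + templates.loc[idx, "end"]) // 2)
            scores = np.maximum(10.0, rng.normal(mu, sd, size=len(idx)))
            for j, (t, c, sc) in enumerate(zip(idx, centers, scores)):
                chrom = templates.at[t, "chrom"]
                start = max(0, int(c) - peak_width // 2)
                rows.append((chrom, start, start + peak_width,
                             f"{background}_{kind}_{j + 1:05d}", float(sc)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])

    peaks: dict[str, list[PeakSet]] = {}
    coverage: dict[str, pd.DataFrame] = {}
    for background in BACKGROUNDS:
        truth = truth_peaks(background)
        reps = []
        for r in range(1, n_reps + 1):
            rep = truth.copy()
            if jitter > 0:
                shift = rng.integers(-jitter, jitter + 1, size=len(rep))
                rep["start"] = np.maximum(0, rep["start"] + shift)
                rep["end"] = rep["end"] + shift
                rep["score"] = np.maximum(
                    5.0, rep["score"] * rng.normal(1.0, 0.05, size=len(rep)))
            rep["name"] = [f"{n}_r{r}" for n in rep["name"]]
            reps.append(PeakSet(rep, label=f"{background}_rep{r}"))
        peaks[background] = reps
        coverage[background] = coverage_from_peaks(
            PeakSet(truth, label=background), height_scale=0.1)
    return peaks, coverage
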