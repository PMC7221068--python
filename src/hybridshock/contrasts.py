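"""The four-way contrast design, ASE-inheritance classification, and modulon
scenario quantification.

Contrast families and their sign conventions:

* ``parents``      — parental orthologs, log2(species A / species B), at one
  temperature; cross-species, so length-and-library normalization.
* ``backgrounds``  — hybrid sub-genome vs the matching parent for one species,
  log2(hybrid / parent); same genome, library-size normalization.
* ``homeologs``    — within-hybrid alleles, log2(allele A / allele B); the two
  allele columns come from one library, so allele-length-only normalization.
* ``temperature``  — cold vs warm within one species/background,
  log2(cold / warm); library-size normalization.

Inheritance classification intersects the parents and homeologs DE sets:
a homeolog pair imbalanced in the hybrid *and* differentially expressed
between the parents in the same direction has inherited its imbalance
(``inherited_ASE``); imbalance without a parental difference is acquired by
hybridization (``acquired_ASE``); a parental difference absent within the
hybrid is attenuated; everything else is conserved. Pairs DE in both contrasts
with opposite signs are classified acquired and flagged ``reversed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hybridshock import degene
from hybridshock.syndata.design import CountTable

FAMILIES = ("parents", "backgrounds", "homeologs", "temperature")
CATEGORIES = ("inherited_ASE", "acquired_ASE", "attenuated", "conserved")

_FAMILY_MODE = {
    "parents": "length_and_library",
    "backgrounds": "library_size",
    "homeologs": "allele_length_only",
    "temperature": "library_size",
}


@dataclass
class ContrastSpec:
    """One contrast of the study design.

    ``species`` selects the gene copy for backgrounds/temperature contrasts;
    ``temperature`` fixes the condition for parents/backgrounds/homeologs;
    ``background`` chooses parent or hybrid samples for temperature contrasts.
    """

    family: str
    temperature: str | None = None
    species: str | None = None
    background: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown contrast family {self.family!r}")
        if not self.name:
            bits = [self.family] + [
                str(v) for v in (self.species, self.background, self.temperature)
                if v is not None]
            self.name = "_".join(bits)

    @property
    def mode(self) -> str:
        return _FAMILY_MODE[self.family]


def _select(table: CountTable, spec: ContrastSpec):
    """Sample columns, group labels and numerator/denominator for a spec."""
    meta = table.sample_meta
    if spec.family == "parents":
        sub = table.select(background="parent", temperature=spec.temperature)
        groups = sub.sample_meta["species"]
        num, den = "A", "B"
    elif spec.family == "homeologs":
        sub = table.select(background="hybrid", temperature=spec.temperature)
        groups = sub.sample_meta["allele"]
        num, den = "A", "B"
    elif spec.family == "backgrounds":
        sub = table.select(species=spec.species, temperature=spec.temperature)
        groups = sub.sample_meta["background"]
        num, den = "hybrid", "parent"
    else:  # temperature
        crit = {}
        if spec.species is not None:
            crit["species"] = spec.species
        if spec.background is not None:
            crit["background"] = spec.background
        sub = table.select(**crit)
        groups = sub.sample_meta["temperature"]
        num, den = "cold", "warm"
    if len(sub.counts.columns) == 0:
        raise ValueError(f"no samples match contrast {spec.name!r}")
    return sub, groups, num, den


def table_dispersions(table: CountTable,
                      shrink: float = 0.0) -> tuple[pd.Series, int]:
    """Per-gene dispersions from every replicate stratum of the whole table.

    Dispersion is a property of the counts, not of one contrast, so it is
    estimated once across all (species, background, allele, temperature)
    strata — at 3 replicates per stratum this multiplies the residual degrees
    of freedom available to each gene. Returns (dispersions, residual df).
    """
    meta = table.sample_meta
    strata = (meta["species"].astype(str) + "/" + meta["background"].astype(str)
              + "/" + meta["allele"].astype(str) + "/"
              + meta["temperature"].astype(str))
    lengths = table.gene_lengths
    if lengths is None:
        lengths = pd.DataFrame(1000.0, index=table.counts.index,
                               columns=table.counts.columns)
    norm = degene.NormalizationSpec.build("length_and_library", table.counts,
                                          lengths)
    alpha = degene.estimate_dispersion(table.counts, norm.factors, strata,
                                       shrink=shrink)
    return alpha, degene.dispersion_df(strata)


def run_contrast(table: CountTable, spec: ContrastSpec,
                 l2fc_min: float = 1.5, padj_max: float = 0.01,
                 dispersions: pd.Series | None = None,
                 df: float | None = None) -> dict:
    """Run one contrast; returns ``{"result": frame, "de": called frame, "spec"}``.

    Dispersions default to the whole-table estimate of
    :func:`table_dispersions` (pass them in when running many contrasts on
    the same table to avoid recomputation).
    """
    sub, groups, num, den = _select(table, spec)
    if dispersions is None:
        dispersions, df = table_dispersions(table)
    lengths = sub.gene_lengths
    if lengths is None and spec.mode != "library_size":
        lengths = pd.DataFrame(1000.0, index=sub.counts.index,
                               columns=sub.counts.columns)
    res = degene.run_de(sub.counts, groups, numerator=num, denominator=den,
                        mode=spec.mode, lengths=lengths,
                        dispersions=dispersions, df=df, name=spec.name)
    de = degene.call_de(res, l2fc_min=l2fc_min, padj_max=padj_max)
    return {"spec": spec, "result": res, "de": de}


def expression_distance(a, b) -> float:
    """Transcriptome distance 1 - Spearman rho (average ranks for ties).

    Range [0, 2]; 0 for identical rankings, 2 for exactly reversed ones.
    Raises on constant vectors, where rho is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("vectors must share a length >= 3")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("Spearman rho undefined for a constant vector")
    rho = stats.spearmanr(a, b).statistic
    return float(1.0 - rho)


# -------------------------------------------------------------- inheritance
def classify_inheritance(parents_de: pd.DataFrame, homeolog_de: pd.DataFrame,
                         universe: pd.Index) -> dict:
    """Classify each ortholog pair of ``universe`` into the four categories.

    ``parents_de`` / ``homeolog_de`` are called-DE frames (index = pair id,
    ``direction`` column). Returns the per-pair call frame and the directional
    Venn counts (per direction: parents-only, both same-direction, homeologs-
    only; reversed-sign pairs are counted with the homeologs-only part of the
    homeolog direction and flagged).
    """
    for de in (parents_de, homeolog_de):
        if len(de) and not de.index.isin(universe).all():
            raise ValueError("DE set not contained in the universe")
        if len(de) and "direction" not in de.columns:
            raise ValueError("DE set lacks direction labels")
    universe = pd.Index(universe)
    p_dir = parents_de["direction"] if len(parents_de) else pd.Series(dtype=object)
    h_dir = homeolog_de["direction"] if len(homeolog_de) else pd.Series(dtype=object)

    calls = pd.DataFrame(index=universe)
    calls["parents_direction"] = p_dir.reindex(universe)
    calls["homeolog_direction"] = h_dir.reindex(universe)
    in_p = calls["parents_direction"].notna()
    in_h = calls["homeolog_direction"].notna()
    same = in_p & in_h & (calls["parents_direction"] == calls["homeolog_direction"])
    reversed_ = in_p & in_h & ~same

    category = np.where(same, "inherited_ASE",
               np.where(in_h, "acquired_ASE",
               np.where(in_p, "attenuated", "conserved")))
    calls["category"] = category
    calls["reversed"] = reversed_

    venn = {}
    for direction in ("up", "down"):
        pd_ = in_p & (calls["parents_direction"] == direction)
        hd_ = in_h & (calls["homeolog_direction"] == direction)
        both = int((pd_ & hd_ & same).sum())
        venn[direction] = {
            "parents_only": int((pd_ & ~(hd_ & same)).sum()),
            "both": both,
            "homeologs_only": int((hd_ & ~(pd_ & same)).sum()),
        }
    counts = calls["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    return {"calls": calls, "venn": venn, "counts": counts,
            "n_reversed": int(reversed_.sum())}


def quantify_modulon_scenarios(calls: pd.DataFrame) -> dict[str, float]:
    """Fractions of the three regulatory outcomes of hybridization.

    * scenario i   — no modulon crosstalk: expression inherited unchanged
      (conserved + inherited_ASE);
    * scenario ii  — modulon blending: parental differences attenuated;
    * scenario iii — novel divergence acquired in the hybrid (the shock class).
    """
    n = len(calls)
    if n == 0:
        raise ValueError("empty universe")
    counts = calls["category"].value_counts()
    i = (counts.get("conserved", 0) + counts.get("inherited_ASE", 0)) / n
    ii = counts.get("attenuated", 0) / n
    iii = counts.get("acquired_ASE", 0) / n
    return {"scenario_i": float(i), "scenario_ii": float(ii),
            "scenario_iii": float(iii)}


# ------------------------------------------------- temperature-dependent ASE
def temperature_dependent_ase(table: CountTable, l2fc_min: float = 1.5,
                              padj_max: float = 0.01) -> dict:
    """Genes whose within-hybrid allele ratio depends on temperature.

    Implemented as an interaction Wald test: the homeolog contrast is fitted
    at each temperature (allele-length-only normalization) and the interaction
    effect is the difference of the two allele log2 ratios with pooled
    standard error; called at ``|l2fc| > l2fc_min`` and ``padj < padj_max``.
    """
    hyb = table.select(background="hybrid")
    temps = sorted(hyb.sample_meta["temperature"].unique())
    if len(temps) < 2:
        raise ValueError("temperature-dependent ASE needs both temperatures")
    dispersions, df = table_dispersions(table)
    per_temp = {}
    for temp in ("warm", "cold"):
        spec = ContrastSpec(family="homeologs", temperature=temp)
        per_temp[temp] = run_contrast(table, spec, l2fc_min=l2fc_min,
                                      padj_max=padj_max,
                                      dispersions=dispersions, df=df)["result"]
    warm, cold = per_temp["warm"], per_temp["cold"]
    l2fc = cold["l2fc"] - warm["l2fc"]
    se = np.sqrt(cold["se"] ** 2 + warm["se"] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = l2fc / se
    p = pd.Series(2.0 * stats.t.sf(np.abs(z), df=df), index=l2fc.index)
    res = pd.DataFrame({
        "base_mean": (cold["base_mean"] + warm["base_mean"]) / 2,
        "l2fc": l2fc, "se": se, "p": p,
        "contrast": "homeolog_x_temperature",
    })
    res["padj"] = degene.adjust_bh(res["p"])
    de = degene.call_de(res, l2fc_min=l2fc_min, padj_max=padj_max)
    return {"result": res, "de": de}


# ---------------------------------------------------------------- batteries
def default_contrast_specs(temperatures=("warm", "cold")) -> list[ContrastSpec]:
    """The full comparison battery of the study design."""
    specs: list[ContrastSpec] = []
    for temp in temperatures:
        specs.append(ContrastSpec("parents", temperature=temp))
        specs.append(ContrastSpec("homeologs", temperature=temp))
        for sp in ("A", "B"):
            specs.append(ContrastSpec("backgrounds", species=sp, temperature=temp))
    for sp in ("A", "B"):
        specs.append(ContrastSpec("temperature", species=sp, background="parent"))
        specs.append(ContrastSpec("temperature", species=sp, background="hybrid"))
    return specs
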