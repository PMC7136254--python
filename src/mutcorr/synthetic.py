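"""Synthetic multi-cancer cohorts and dose-response surfaces.

The screen's real inputs are per-cancer somatic mutation tables and
expression z-score matrices. This module generates cohorts with the same
statistical structure so the whole pipeline is testable without downloads:

* per-sample mutation counts are negative-binomial — pan-cancer mutation
  loads are overdispersed by orders of magnitude between samples of one
  cancer type, which a Poisson cannot show;
* mutation records are spread multinomially over variant classes and
  uniformly over a gene universe;
* background gene expression is i.i.d. standard normal per sample (already a
  z-score under the cohort reference);
* *planted* genes carry a prescribed Spearman correlation with mutation
  load, via a Gaussian copula on the load ranks: with
  ``r = 2 sin(pi * rho_s / 6)`` the pair (expression, load rank) is
  bivariate-normal-like with Spearman rho_s in the large-n limit, so the
  realized rank correlation converges to the target as n grows. At
  target_rho = +-1 the expression is an exactly monotone function of load
  rank and the realized Spearman correlation is +-1 for any n.

Dose-response surfaces follow Hill curves per single agent; the combination
is Bliss independence sharpened by a synergy exponent,
``E_AB = 1 - (1 - E_bliss)^alpha`` (alpha = 1 recovers Bliss, alpha > 1 is
super-Bliss at every dose pair, and effects stay in [0, 1]).

All outputs are deterministic functions of the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .gmt import write_gmt
from .synergy import DoseResponseDesign

#: Variant-class order used by class_mix.
CLASS_ORDER = ("missense", "silent", "nonsense", "insertion", "deletion")

#: Realistic exome class mix: substitutions dominate, ~2.3:1
#: missense:silent, a thin tail of truncating and indel events.
DEFAULT_CLASS_MIX = (0.58, 0.25, 0.07, 0.04, 0.06)


@dataclass(frozen=True)
class PlantedGene:
    """Ground-truth gene: its expression is constructed to carry Spearman
    correlation ``target_rho`` with mutation load in one cancer type."""

    gene: str
    cancer_type: str
    target_rho: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_rho <= 1.0:
            raise ValueError(f"target_rho must be in [-1, 1], got {self.target_rho}")


@dataclass(frozen=True)
class CancerType:
    """One synthetic cohort. load_mean/load_dispersion override the
    cohort-wide defaults when set."""

    name: str
    n_samples: int
    load_mean: float | None = None
    load_dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError(f"{self.name}: n_samples must be >= 10, "
                             f"got {self.n_samples}")


@dataclass
class CohortSpec:
    """Specification of a multi-cancer synthetic cohort.

    Defaults emulate a pan-cancer exome screen: ~210 mutation events per
    sample on average (a multi-cancer average of roughly 1.5M somatic
    mutations over ~7k exomes) with strong negative-binomial overdispersion
    (dispersion = NB shape k; variance = mu + mu^2/k, so k = 0.7 spreads
    per-sample loads over orders of magnitude).
    """

    cancer_types: Sequence[CancerType]
    n_genes: int = 5000
    load_mean: float = 210.0
    load_dispersion: float = 0.7
    class_mix: Sequence[float] = DEFAULT_CLASS_MIX
    planted: Sequence[PlantedGene] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cancer_types:
            raise ValueError("need at least one cancer type")
        names = [c.name for c in self.cancer_types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cancer type names")
        if len(self.class_mix) != len(CLASS_ORDER):
            raise ValueError(f"class_mix needs {len(CLASS_ORDER)} probabilities "
                             f"(order {CLASS_ORDER})")
        if any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix probabilities must be non-negative")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {sum(self.class_mix)}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        seen: set[tuple[str, str]] = set()
        for p in self.planted:
            if p.cancer_type not in names:
                raise ValueError(f"planted gene {p.gene}: unknown cancer type "
                                 f"{p.cancer_type}")
            key = (p.cancer_type, p.gene)
            if key in seen:
                raise ValueError(f"planted gene {p.gene} duplicated in "
                                 f"{p.cancer_type}")
            seen.add(key)


def _planted_expression(loads: np.ndarray, target_rho: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Expression vector with Spearman correlation ~ target_rho to loads.

    Gaussian copula: z_load = Phi^-1((rank - 0.5)/n) on average load ranks,
    expression = r * z_load + sqrt(1 - r^2) * noise with
    r = 2 sin(pi * target_rho / 6) (the bivariate-normal Spearman/Pearson
    relation). target_rho = +-1 short-circuits to an exactly monotone map.
    """
    n = len(loads)
    ranks = stats.rankdata(loads)
    z_load = stats.norm.ppf((ranks - 0.5) / n)
    if abs(target_rho) >= 1.0:
        return math.copysign(1.0, target_rho) * z_load
    r = 2.0 * math.sin(math.pi * target_rho / 6.0)
    return r * z_load + math.sqrt(1.0 - r * r) * rng.standard_normal(n)


def simulate_cohort(spec: CohortSpec) -> tuple[dict[str, pd.DataFrame],
                                               dict[str, ExpressionMatrix],
                                               pd.DataFrame]:
    """Generate the screen's inputs for every cancer type in ``spec``.

    Returns ``(mutations, expression, truth)``:

    * ``mutations[name]`` — MAF-like records (sample, gene, variant_class);
      each sample's record count is its negative-binomial mutation load,
      classes multinomial over ``class_mix``, genes uniform over the
      universe (background symbols ``G000001``... plus planted symbols).
    * ``expression[name]`` — z-score ExpressionMatrix over the same samples:
      background genes i.i.d. N(0, 1), planted genes via the load-rank
      copula.
    * ``truth`` — planted-gene table (gene, cancer_type, target_rho).
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(spec.cancer_types))
    background = [f"G{i:06d}" for i in range(1, spec.n_genes + 1)]
    class_probs = np.asarray(spec.class_mix, dtype=float)

    mutations: dict[str, pd.DataFrame] = {}
    expression: dict[str, ExpressionMatrix] = {}
    for ct, ss in zip(spec.cancer_types, children):
        rng = np.random.default_rng(ss)
        n = ct.n_samples
        samples = [f"{ct.name}-S{i:04d}" for i in range(1, n + 1)]
        planted_here = [p for p in spec.planted if p.cancer_type == ct.name]
        universe = background + [p.gene for p in planted_here
                                 if p.gene not in set(background)]

        mu = ct.load_mean if ct.load_mean is not None else spec.load_mean
        k = (ct.load_dispersion if ct.load_dispersion is not None
             else spec.load_dispersion)
        if mu <= 0 or k <= 0:
            raise ValueError(f"{ct.name}: load_mean and load_dispersion must "
                             "be positive")
        loads = rng.negative_binomial(k, k / (k + mu), size=n)

        total = int(loads.sum())
        gene_idx = rng.integers(0, len(universe), size=total)
        classes = rng.choice(len(CLASS_ORDER), size=total, p=class_probs)
        mutations[ct.name] = pd.DataFrame({
            "sample": np.repeat(samples, loads),
            "gene": np.asarray(universe, dtype=object)[gene_idx],
            "variant_class": np.asarray(CLASS_ORDER, dtype=object)[classes],
        })

        X = rng.standard_normal((spec.n_genes, n))
        rows = [pd.DataFrame(X, index=background, columns=samples)]
        if planted_here:
            P = np.vstack([_planted_expression(loads, p.target_rho, rng)
                           for p in planted_here])
            rows.append(pd.DataFrame(P, index=[p.gene for p in planted_here],
                                     columns=samples))
        values = pd.concat(rows)
        expression[ct.name] = ExpressionMatrix(
            values, is_zscore=True, reference="synthetic standard-normal background")

    truth = pd.DataFrame([(p.gene, p.cancer_type, p.target_rho)
                          for p in spec.planted],
                         columns=["gene", "cancer_type", "target_rho"])
    return mutations, expression, truth


def simulate_dose_response(ec50_a: float, hill_a: float,
                           ec50_b: float, hill_b: float,
                           ratio: float, doses_a: Sequence[float],
                           synergy_alpha: float = 1.0,
                           noise_sd: float = 0.0, seed: int = 0,
                           drug_a: str = "drugA", drug_b: str = "drugB"
                           ) -> DoseResponseDesign:
    """Constant-ratio dose-response surface with tunable synergy.

    Single agents follow Hill curves E(d) = d^h / (d^h + EC50^h); at each
    rung the combination effect is ``1 - (1 - E_bliss)^synergy_alpha`` with
    E_bliss = E_A + E_B - E_A*E_B (alpha = 1 is exact Bliss independence).
    Gaussian noise of sd ``noise_sd`` is added to every survival value, then
    clipped to [0, 1]. Deterministic under ``seed``.
    """
    if min(ec50_a, hill_a, ec50_b, hill_b, ratio) <= 0:
        raise ValueError("EC50s, Hill slopes and ratio must be positive")
    if synergy_alpha <= 0:
        raise ValueError("synergy_alpha must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    doses_a = np.asarray(doses_a, dtype=float)
    if doses_a.ndim != 1 or len(doses_a) < 1 or np.any(doses_a <= 0):
        raise ValueError("doses_a must be a non-empty positive dose ladder")
    if np.any(np.diff(doses_a) <= 0):
        raise ValueError("dose ladder must be strictly increasing")

    doses_b = ratio * doses_a
    e_a = doses_a ** hill_a / (doses_a ** hill_a + ec50_a ** hill_a)
    e_b = doses_b ** hill_b / (doses_b ** hill_b + ec50_b ** hill_b)
    e_bliss = e_a + e_b - e_a * e_b
    e_ab = 1.0 - (1.0 - e_bliss) ** synergy_alpha

    rng = np.random.default_rng(seed)
    surv = np.column_stack([1.0 - e_a, 1.0 - e_b, 1.0 - e_ab])
    if noise_sd > 0:
        surv = surv + rng.normal(0.0, noise_sd, size=surv.shape)
    surv = np.clip(surv, 0.0, 1.0)

    rows = pd.DataFrame({
        "dose_a": doses_a, "dose_b": doses_b,
        "survival_a": surv[:, 0], "survival_b": surv[:, 1],
        "survival_ab": surv[:, 2],
    })
    return DoseResponseDesign(drug_a, drug_b, ratio, rows,
                              metadata={"synergy_alpha": synergy_alpha,
                                        "noise_sd": noise_sd, "seed": seed})


def write_fixture_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    """Write fixture gene sets to GMT (duplicate set names impossible in a
    mapping; duplicate members within a set rejected)."""
    write_gmt(sets, path, description="synthetic fixture")


def make_cell_cycle_fixture(n_pathway: int = 124, n_mcm: int = 6,
                            n_cdk: int = 19) -> dict[str, list[str]]:
    """Synthetic stand-in for a cell-cycle pathway with nested complexes.

    Builds a ``cell_cycle`` set of ``n_pathway`` symbols containing two
    disjoint complexes: an MCM-like helicase complex (``MCM2``..``MCM7``
    style, ``n_mcm`` members) and a CDK4/6-like complex (``n_cdk`` members,
    anchored by CDK4, CDK6, TP53, RB1, ATM, ATR). Symbols are synthetic;
    only the set sizes and nesting mirror the real pathway structure.
    """
    mcm = [f"MCM{i}" for i in range(2, 2 + n_mcm)]
    cdk_anchor = ["CDK4", "CDK6", "TP53", "RB1", "ATM", "ATR"]
    cdk = (cdk_anchor + [f"CDKC{i:02d}" for i in range(1, n_cdk - len(cdk_anchor) + 1)])[:n_cdk]
    rest = [f"CC{i:03d}" for i in range(1, n_pathway - n_mcm - n_cdk + 1)]
    pathway = mcm + cdk + rest
    assert len(pathway) == n_pathway
    return {"cell_cycle": pathway, "MCM": mcm, "CDK4_6": cdk}


def write_cohort(mutations: Mapping[str, pd.DataFrame],
                 expression: Mapping[str, ExpressionMatrix],
                 truth: pd.DataFrame, outdir: str | Path) -> dict[str, dict[str, str]]:
    """Write a simulated cohort as the TSV files the pipeline consumes.

    Per cancer type: ``<name>.mutations.tsv`` (MAF-like) and
    ``<name>.expression.tsv`` (genes x samples z-scores); plus
    ``truth.tsv``. Returns {cancer: {"mutations": path, "expression": path}}.
    """
    from .expression import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, str]] = {}
    for name, records in mutations.items():
        mpath = outdir / f"{name}.mutations.tsv"
        epath = outdir / f"{name}.expression.tsv"
        records.to_csv(mpath, sep="\t", index=False)
        write_matrix(expression[name], epath)
        paths[name] = {"mutations": str(mpath), "expression": str(epath)}
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return paths
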