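"""Combination index from constant-ratio dose-response data.

Two drugs are escalated together at a fixed dose ratio (e.g. a PARP
inhibitor with a CDK4/6 inhibitor at 1:4). Cell survival is measured for
each single agent and for the combination; the effect of an arm is the
fraction affected, E = 1 - survival. The combination index at each dose pair
is

    CI = (E_A + E_B) / E_AB

with E_AB the combination's effect (also reported as Fa, the fraction
affected by the combination). CI < 1 is synergistic, CI > 1 antagonistic,
CI = 1 "similar" (additive under this formula). Note the formula is
effect-additive, not independence-based: an exact Bliss-independent surface
always yields CI >= 1, so CI < 1 indicates super-Bliss interaction.

Replicates are averaged before CI; per-replicate CIs can be computed on the
long-format table for dispersion reporting. A xenograft tumor-volume helper
(0.52 * L * W^2 from caliper diameters) is included.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CI_TOL = 1e-9


@dataclass
class DoseResponseDesign:
    """Constant-ratio dose-response table, replicate-averaged.

    ``rows`` columns: dose_a, dose_b, survival_a, survival_b, survival_ab
    (survivals in [0, 1]). dose_b/dose_a must be constant across rows
    (relative tolerance 1e-9).
    """

    drug_a: str
    drug_b: str
    ratio: float  # dose_b : dose_a
    rows: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"dose_a", "dose_b", "survival_a", "survival_b", "survival_ab"}
        missing = need - set(self.rows.columns)
        if missing:
            raise ValueError(f"dose-response rows missing columns: {sorted(missing)}")
        da = self.rows["dose_a"].to_numpy(dtype=float)
        db = self.rows["dose_b"].to_numpy(dtype=float)
        if np.any(da <= 0) or np.any(db <= 0):
            raise ValueError("doses must be positive")
        if not np.allclose(db / da, self.ratio, rtol=1e-9, atol=0.0):
            raise ValueError(
                f"dose_b/dose_a is not the constant ratio {self.ratio} "
                f"(observed {sorted(set(np.round(db / da, 6)))})")
        surv = self.rows[["survival_a", "survival_b", "survival_ab"]].to_numpy(float)
        if np.any((surv < 0) | (surv > 1)):
            bad = int(np.argwhere((surv < 0) | (surv > 1))[0, 0])
            raise ValueError(f"survival outside [0, 1] in row {bad}")


def effects_from_survival(design: DoseResponseDesign) -> pd.DataFrame:
    """Per-row effects E = 1 - survival for each arm; Fa = E_AB."""
    out = design.rows[["dose_a", "dose_b"]].copy()
    out["E_A"] = 1.0 - design.rows["survival_a"]
    out["E_B"] = 1.0 - design.rows["survival_b"]
    out["E_AB"] = 1.0 - design.rows["survival_ab"]
    out["Fa"] = out["E_AB"]
    return out


def combination_index(e_a: float, e_b: float, e_ab: float
                      ) -> tuple[float, Literal["synergistic", "antagonistic",
                                                "similar", "NA"]]:
    """CI = (E_A + E_B)/E_AB with its verdict.

    Undefined when the combination shows no effect (E_AB = 0): returns
    (nan, "NA") rather than a silent number.
    """
    for name, e in (("E_A", e_a), ("E_B", e_b), ("E_AB", e_ab)):
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"{name} = {e} outside [0, 1]")
    if e_ab <= 0.0:
        return math.nan, "NA"
    ci = (e_a + e_b) / e_ab
    if abs(ci - 1.0) <= _CI_TOL:
        return ci, "similar"
    return ci, "synergistic" if ci < 1.0 else "antagonistic"


@dataclass
class SynergyResult:
    """CI curve of one constant-ratio design: per-row (Fa, CI) sorted by Fa
    ascending, plus the CI range over defined rows."""

    drug_a: str
    drug_b: str
    ratio: float
    table: pd.DataFrame  # dose_a, dose_b, E_A, E_B, E_AB, Fa, CI, verdict
    ci_min: float
    ci_max: float


def ci_curve(design: DoseResponseDesign) -> SynergyResult:
    """Compute the (Fa, CI) curve for a constant-ratio design.

    Needs at least 3 dose rows. Rows with E_AB = 0 propagate as NA and are
    excluded from the CI range.
    """
    if len(design.rows) < 3:
        raise ValueError(f"need >= 3 dose rows, got {len(design.rows)}")
    eff = effects_from_survival(design)
    ci_verdict = [combination_index(a, b, ab)
                  for a, b, ab in zip(eff["E_A"], eff["E_B"], eff["E_AB"])]
    eff["CI"] = [cv[0] for cv in ci_verdict]
    eff["verdict"] = [cv[1] for cv in ci_verdict]
    eff = eff.sort_values(["Fa", "dose_a"], kind="stable").reset_index(drop=True)
    defined = eff["CI"].dropna()
    if defined.empty:
        ci_min = ci_max = math.nan
    else:
        ci_min, ci_max = float(defined.min()), float(defined.max())
    return SynergyResult(design.drug_a, design.drug_b, design.ratio,
                         eff, ci_min, ci_max)


def read_dose_response(path: str | Path, drug_a: str, drug_b: str,
                       ratio: float, **metadata) -> tuple[DoseResponseDesign,
                                                          pd.DataFrame]:
    """Read a long-format dose-response CSV and build a design.

    Expected columns: ``drug, dose, replicate, survival`` where ``drug`` is
    ``drug_a``, ``drug_b`` or ``"<drug_a>+<drug_b>"``; combination rows carry
    the dose of drug A. Each arm must expose the same dose-ladder length.
    Returns the replicate-averaged design plus a per-replicate CI table for
    dispersion reporting.
    """
    df = pd.read_csv(path)
    missing = {"drug", "dose", "replicate", "survival"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    combo = f"{drug_a}+{drug_b}"
    arms = {}
    for arm, name in (("a", drug_a), ("b", drug_b), ("ab", combo)):
        sub = df[df["drug"] == name]
        if sub.empty:
            raise ValueError(f"{path}: no rows for arm {name!r}")
        arms[arm] = sub

    def ladder(sub: pd.DataFrame) -> pd.DataFrame:
        avg = sub.groupby("dose", as_index=False)["survival"].mean()
        return avg.sort_values("dose").reset_index(drop=True)

    la, lb, lab = ladder(arms["a"]), ladder(arms["b"]), ladder(arms["ab"])
    if not (len(la) == len(lb) == len(lab)):
        raise ValueError(f"{path}: arms have different dose-ladder lengths "
                         f"({len(la)}/{len(lb)}/{len(lab)})")
    dose_a = la["dose"].to_numpy(float)
    if not np.allclose(lb["dose"].to_numpy(float), ratio * dose_a, rtol=1e-9):
        raise ValueError(f"{path}: drug-B ladder is not ratio x drug-A ladder")
    rows = pd.DataFrame({
        "dose_a": dose_a, "dose_b": ratio * dose_a,
        "survival_a": la["survival"], "survival_b": lb["survival"],
        "survival_ab": lab["survival"],
    })
    design = DoseResponseDesign(drug_a, drug_b, ratio, rows, metadata)

    # per-replicate CIs (dispersion only; NA rows kept as NaN)
    per_rep = []
    for rep in sorted(df["replicate"].unique()):
        sub = df[df["replicate"] == rep]
        try:
            sa = sub[sub.drug == drug_a].set_index("dose")["survival"]
            sb = sub[sub.drug == drug_b].set_index("dose")["survival"]
            sab = sub[sub.drug == combo].set_index("dose")["survival"]
        except KeyError:
            continue
        for d in dose_a:
            if d in sa.index and ratio * d in sb.index and d in sab.index:
                e_a, e_b, e_ab = 1 - sa[d], 1 - sb[ratio * d], 1 - sab[d]
                ci = (e_a + e_b) / e_ab if e_ab > 0 else math.nan
                per_rep.append((rep, d, ci))
    rep_table = pd.DataFrame(per_rep, columns=["replicate", "dose_a", "CI"])
    return design, rep_table


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Xenograft tumor volume (mm^3) from caliper diameters: 0.52 * L * W^2,
    L the longest and W the shortest diameter. If called with L < W the two
    are swapped with a warning rather than failing."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("tumor diameters must be positive")
    if length_mm < width_mm:
        logger.warning("L (%.3g) < W (%.3g): swapping diameters",
                       length_mm, width_mm)
        length_mm, width_mm = width_mm, length_mm
    return 0.52 * length_mm * width_mm ** 2
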