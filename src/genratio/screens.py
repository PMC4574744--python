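"""Dose-response processing and sensitivity calling.

Converts raw viability-screen measurements (dose, % inhibition) into the
three-class sensitivity labels the ratio classifier trains on, aggregates
calls across screens by majority vote, tests lineages for enrichment of
sensitivity, and derives responder labels from xenograft tumor-volume series.

Conventions: inhibition is expressed as % of untreated control, where 0 means
growth at the untreated rate and 100 means total kill.  Amax is the upper
plateau of a variable-slope sigmoid fit; EC50 its inflection dose; IC50 the
dose where the fitted curve crosses 50% inhibition, set to the maximum tested
dose when the plateau never reaches 50%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import fisher_exact

__all__ = [
    "DoseResponse",
    "SigmoidFit",
    "SensitivityCall",
    "ConsensusCall",
    "InVivoResponse",
    "sigmoid_inhibition",
    "fit_dose_response",
    "call_sensitivity",
    "consensus_call",
    "lineage_enrichment",
    "in_vivo_response",
    "read_dose_response",
    "calls_to_frame",
]

SENSITIVE = "sensitive"
INTERMEDIATE = "intermediate"
INSENSITIVE = "insensitive"
CONFLICT = "conflict"

#: Amax (% inhibition) at or above which a line is called sensitive.
SENSITIVE_AMAX = 70.0
#: Amax at or below which a line is called insensitive.
INSENSITIVE_AMAX = 50.0


@dataclass
class DoseResponse:
    """One dose-response curve for one cell line in one screen."""

    cell_line_id: str
    screen_id: str
    doses: np.ndarray  # molar, strictly ascending
    inhibition: np.ndarray  # % of untreated control
    replicate: int = 0

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.doses.shape != self.inhibition.shape:
            raise ValueError("doses and inhibition must have equal length")
        if self.doses.size < 3:
            raise ValueError("need at least 3 dose points for curve fitting")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly ascending")
        if not np.all(self.doses > 0):
            raise ValueError("doses must be positive (molar)")
        if not np.all(np.isfinite(self.inhibition)):
            raise ValueError("inhibition values must be finite")


@dataclass
class SigmoidFit:
    """Parameters of a variable-slope sigmoid fit to a dose-response curve."""

    a_max: float
    ec50: float
    ic50: float
    hill: float
    converged: bool
    ec50_extrapolated: bool = False


@dataclass
class SensitivityCall:
    cell_line_id: str
    screen_id: str
    call: str


@dataclass
class ConsensusCall:
    cell_line_id: str
    call: str
    n_screens: int


@dataclass
class InVivoResponse:
    """Anti-tumor activity of one treated xenograft model vs vehicle control."""

    model_id: str
    tv_treated_initial: float
    tv_treated_final: float
    tv_control_initial: float
    tv_control_final: float
    t_over_c: float | None = field(default=None)  # %, only when treated arm grew
    regression: float | None = field(default=None)  # %, only when treated arm shrank
    responder: bool = False
    valid: bool = True


def sigmoid_inhibition(dose: np.ndarray, a_max: float, ec50: float, hill: float) -> np.ndarray:
    """Variable-slope sigmoid with lower plateau fixed at 0% inhibition."""
    dose = np.asarray(dose, dtype=float)
    return a_max / (1.0 + (ec50 / dose) ** hill)


def _ic50_from_fit(a_max: float, ec50: float, hill: float, max_dose: float) -> float:
    # Plateau below 50% inhibition: IC50 pinned at the maximum tested dose.
    if a_max < 50.0:
        return max_dose
    if a_max == 50.0:
        return min(max_dose, ec50)
    ic50 = ec50 / (a_max / 50.0 - 1.0) ** (1.0 / hill)
    return min(ic50, max_dose)


def fit_dose_response(curve: DoseResponse) -> SigmoidFit:
    """Least-squares variable-slope sigmoid fit of one dose-response curve.

    Multi-start initialization from data quantiles; on non-convergence the
    fit falls back to ``a_max = max(observed inhibition)`` with
    ``converged=False``.
    """
    doses, inhib = curve.doses, curve.inhibition
    max_dose = float(doses[-1])
    log_d = np.log(doses)

    a0 = max(float(np.max(inhib)), 1.0)

    def model(ld: np.ndarray, a: float, log_ec50: float, h: float) -> np.ndarray:
        return a / (1.0 + np.exp(-h * (ld - log_ec50)))

    # EC50 starts: the interpolated half-maximum crossing plus dose quantiles
    half = a0 / 2.0
    above = np.flatnonzero(inhib >= half)
    starts = list(np.quantile(log_d, [0.25, 0.5, 0.75]))
    if above.size and above[0] > 0:
        i = above[0]
        frac = (half - inhib[i - 1]) / max(inhib[i] - inhib[i - 1], 1e-12)
        starts.append(log_d[i - 1] + frac * (log_d[i] - log_d[i - 1]))
    elif above.size:
        starts.append(log_d[0])
    lo = [0.0, log_d[0] - np.log(1e3), 0.05]
    hi = [200.0, log_d[-1] + np.log(1e3), 20.0]

    best = None
    best_sse = np.inf
    for le0 in starts:
        for h0 in (0.5, 1.0, 2.0, 4.0):
            try:
                popt, _ = curve_fit(
                    model,
                    log_d,
                    inhib,
                    p0=[a0, le0, h0],
                    bounds=(lo, hi),
                    maxfev=5000,
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((model(log_d, *popt) - inhib) ** 2))
            if sse < best_sse:
                best_sse = sse
                best = [popt[0], float(np.exp(popt[1])), popt[2]]
                if best_sse < 1e-16:
                    break
        if best_sse < 1e-16:
            break

    # the no-response model is always a candidate (flat data defeats the
    # optimizer's gradient steps)
    zero_sse = float(np.sum(inhib**2))
    if zero_sse < best_sse:
        best_sse = zero_sse
        best = [0.0, max_dose, 1.0]

    if best is None:
        a_fallback = float(np.max(inhib))
        return SigmoidFit(
            a_max=a_fallback,
            ec50=max_dose,
            ic50=max_dose if a_fallback < 50.0 else max_dose,
            hill=1.0,
            converged=False,
        )

    a_max, ec50, hill = (float(v) for v in best)
    ic50 = _ic50_from_fit(a_max, ec50, hill, max_dose)
    extrapolated = not (doses[0] <= ec50 <= max_dose)
    return SigmoidFit(
        a_max=a_max,
        ec50=ec50,
        ic50=float(ic50),
        hill=hill,
        converged=True,
        ec50_extrapolated=bool(extrapolated),
    )


def call_sensitivity(a_max: float) -> str:
    """Three-way sensitivity call from Amax: >=70 sensitive, <=50 insensitive."""
    if not np.isfinite(a_max):
        raise ValueError("a_max must be finite")
    if a_max >= SENSITIVE_AMAX:
        return SENSITIVE
    if a_max <= INSENSITIVE_AMAX:
        return INSENSITIVE
    return INTERMEDIATE


def consensus_call(calls: Sequence[SensitivityCall | str]) -> ConsensusCall:
    """Majority vote of per-screen calls for one cell line.

    A call wins only with a strict majority of the non-missing votes;
    otherwise the consensus is ``conflict``.  Intermediate votes participate
    as their own class.  The result does not depend on input order.
    """
    names = [c.call if isinstance(c, SensitivityCall) else c for c in calls]
    names = [c for c in names if c is not None and c == c]  # drop missing/NaN
    if not names:
        raise ValueError("consensus requires at least one non-missing call")
    line_id = next(
        (c.cell_line_id for c in calls if isinstance(c, SensitivityCall)), ""
    )
    counts = Counter(names)
    top_call, top_n = counts.most_common(1)[0]
    if top_n * 2 > len(names):
        return ConsensusCall(cell_line_id=line_id, call=top_call, n_screens=len(names))
    return ConsensusCall(cell_line_id=line_id, call=CONFLICT, n_screens=len(names))


def lineage_enrichment(
    consensus: Iterable[ConsensusCall],
    lineages: Mapping[str, str],
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-lineage Fisher's exact enrichment of sensitivity and insensitivity.

    Only sensitive/insensitive consensus calls enter the 2x2 tables
    (conflicting and intermediate lines are removed first); lineages with
    fewer than ``min_n`` such lines are excluded.  Each lineage is tested
    one-sided in both directions against the rest of the panel.
    """
    rows = [
        (c.cell_line_id, lineages.get(c.cell_line_id), c.call)
        for c in consensus
        if c.call in (SENSITIVE, INSENSITIVE)
    ]
    df = pd.DataFrame(rows, columns=["cell_line_id", "lineage", "call"]).dropna(
        subset=["lineage"]
    )
    total_sens = int((df["call"] == SENSITIVE).sum())
    total = len(df)
    out = []
    for lineage, grp in df.groupby("lineage"):
        n = len(grp)
        if n < min_n:
            continue
        a = int((grp["call"] == SENSITIVE).sum())  # lineage sensitive
        b = n - a
        c = total_sens - a
        d = (total - n) - c
        table = [[a, b], [c, d]]
        _, p_sens = fisher_exact(table, alternative="greater")
        _, p_insens = fisher_exact(table, alternative="less")
        out.append(
            {
                "lineage": lineage,
                "n": n,
                "response_rate": a / n,
                "p_sensitive": float(p_sens),
                "p_insensitive": float(p_insens),
            }
        )
    return (
        pd.DataFrame(out, columns=["lineage", "n", "response_rate", "p_sensitive", "p_insensitive"])
        .sort_values("response_rate", ascending=False)
        .reset_index(drop=True)
    )


def in_vivo_response(
    model_id: str,
    tv_treated_initial: float,
    tv_treated_final: float,
    tv_control_initial: float,
    tv_control_final: float,
) -> InVivoResponse:
    """Xenograft responder call from arm-level mean tumor volumes.

    %T/C = 100 * dT / dC (only when the treated arm grew, dT >= 0);
    %REG  = 100 * dT / T_initial (only when it shrank, dT < 0).
    A model is a responder on tumor stasis (%T/C < 10) or any regression
    (%REG < 10, which every negative regression satisfies).
    """
    d_treated = tv_treated_final - tv_treated_initial
    d_control = tv_control_final - tv_control_initial
    res = InVivoResponse(
        model_id=model_id,
        tv_treated_initial=tv_treated_initial,
        tv_treated_final=tv_treated_final,
        tv_control_initial=tv_control_initial,
        tv_control_final=tv_control_final,
    )
    if d_treated < 0:
        res.regression = 100.0 * d_treated / tv_treated_initial
        res.responder = res.regression < 10.0
        return res
    if d_control <= 0:
        res.valid = False  # %T/C undefined without control-arm growth
        return res
    res.t_over_c = 100.0 * d_treated / d_control
    res.responder = res.t_over_c < 10.0
    return res


def read_dose_response(path: str, sep: str = "\t") -> list[DoseResponse]:
    """Read long-format dose-response text into per-(line, screen) curves.

    Expected columns: cell_line_id, screen_id, dose, inhibition and
    optionally replicate.  Replicate curves are averaged per dose before
    fitting.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"cell_line_id", "screen_id", "dose", "inhibition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose-response table missing columns: {sorted(missing)}")
    curves = []
    for (line, screen), grp in df.groupby(["cell_line_id", "screen_id"], sort=True):
        mean = grp.groupby("dose", sort=True)["inhibition"].mean()
        curves.append(
            DoseResponse(
                cell_line_id=str(line),
                screen_id=str(screen),
                doses=mean.index.to_numpy(dtype=float),
                inhibition=mean.to_numpy(dtype=float),
            )
        )
    return curves


def calls_to_frame(
    per_screen: Iterable[SensitivityCall], consensus: Iterable[ConsensusCall]
) -> pd.DataFrame:
    """Wide table of per-screen calls plus the consensus column."""
    per = pd.DataFrame(
        [(c.cell_line_id, c.screen_id, c.call) for c in per_screen],
        columns=["cell_line_id", "screen_id", "call"],
    )
    wide = per.pivot_table(
        index="cell_line_id", columns="screen_id", values="call", aggfunc="first"
    )
    cons = pd.Series(
        {c.cell_line_id: c.call for c in consensus}, name="consensus"
    )
    out = wide.join(cons)
    out.columns.name = None
    return out.reset_index()
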