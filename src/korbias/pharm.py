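"""Dose–response fitting and operational-model bias quantification.

Signaling bias is quantified with the Black–Leff operational model.  For each
ligand and pathway the response is

    B = 10^(X·n) · 10^(logτ·n)
    Y = Emax · B / [B + (10^X + 10^K_A)^n]

with X the log10 molar agonist concentration, τ the operational efficacy,
K_A the functional dissociation constant (as log10 molar), n a Hill slope
shared across ligands within a pathway, and Emax the system maximum (fixed to
100 when responses are normalized to a reference full agonist).

The pathway-specific agonism summary is the transduction coefficient
log(τ/K_A) = logτ − logK_A.  Bias analysis proceeds by reference
normalization within each pathway, Δlog(τ/K_A) = log(τ/K_A)_ligand −
log(τ/K_A)_reference, then the between-pathway difference
ΔΔlog(τ/K_A) = Δlog(τ/K_A)_pathway1 − Δlog(τ/K_A)_pathway2, and the bias
factor 10^ΔΔlog(τ/K_A) with a t-based confidence interval symmetric in log10.

For a full agonist τ and K_A trade off and only log(τ/K_A) is well
determined; fits bound logτ (default ≤ 3) and always report log(τ/K_A) with
its standard error from the joint covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import lmfit
from scipy import stats

REQUIRED_COLUMNS = ("ligand", "pathway", "replicate", "log_conc_M", "response")

_FIT_KWS = dict(xtol=1e-13, ftol=1e-13, gtol=1e-13)


def validate_dose_response(df: pd.DataFrame, min_concentrations: int = 4) -> pd.DataFrame:
    """Check the tidy dose–response table; returns the validated frame."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dose–response table lacks columns {missing}")
    if not np.all(np.isfinite(df["response"])):
        raise ValueError("responses must be finite")
    counts = df.groupby(["ligand", "pathway"])["log_conc_M"].nunique()
    thin = counts[counts < min_concentrations]
    if not thin.empty:
        raise ValueError(
            f"need ≥{min_concentrations} distinct concentrations per (ligand, pathway); "
            f"violated by {list(thin.index)}"
        )
    return df


# ---------------------------------------------------------------------------
# Reference normalization and logistic fits
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Four-parameter (or fixed-slope) log(agonist) vs. response fit."""

    ligand: str
    pathway: str
    bottom: float
    top: float
    logec50: float
    hill: float
    se: dict[str, float]
    flags: list[str] = field(default_factory=list)

    @property
    def ec50(self) -> float:
        """EC50 in molar."""
        return 10.0 ** self.logec50


def _logistic(x, bottom, top, logec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - x) * hill))


def fit_logistic(
    df: pd.DataFrame, hill_fixed: float | None = None
) -> dict[tuple[str, str], LogisticFit]:
    """Least-squares logistic fit per (ligand, pathway) group.

    ``hill_fixed`` pins the slope (e.g. 1.0); otherwise it is free.  Fits that
    do not converge or are degenerate (flat response) are returned flagged
    rather than raising.
    """
    out = {}
    for (ligand, pathway), g in df.groupby(["ligand", "pathway"]):
        x = g["log_conc_M"].to_numpy(dtype=float)
        y = g["response"].to_numpy(dtype=float)
        flags: list[str] = []
        if np.ptp(y) < 1e-9:
            out[(ligand, pathway)] = LogisticFit(
                ligand, pathway, float(y.mean()), float(y.mean()), np.nan,
                hill_fixed or np.nan, {}, ["degenerate_flat"],
            )
            continue
        model = lmfit.Model(_logistic)
        params = model.make_params(
            bottom=float(y.min()), top=float(y.max()),
            logec50=float(np.median(x)), hill=hill_fixed or 1.0,
        )
        if hill_fixed is not None:
            params["hill"].set(vary=False)
        else:
            params["hill"].set(min=0.1, max=10.0)
        res = model.fit(y, params, x=x, method="leastsq", fit_kws=_FIT_KWS)
        if not res.success:
            flags.append("fit_failed")
        p = res.params
        se = {k: (p[k].stderr if p[k].stderr is not None else np.nan) for k in p}
        if not (x.min() - 2.0 <= p["logec50"].value <= x.max() + 2.0):
            flags.append("logec50_outside_range")
        out[(ligand, pathway)] = LogisticFit(
            ligand, pathway, float(p["bottom"].value), float(p["top"].value),
            float(p["logec50"].value), float(p["hill"].value), se, flags,
        )
    return out


def normalize_to_reference(df: pd.DataFrame, reference_ligand: str) -> pd.DataFrame:
    """Rescale responses so the reference ligand spans 0–100% in each pathway.

    Within each pathway the reference's logistic fit defines the scale: its
    fitted baseline maps to 0% and its fitted plateau to 100%.  Normalizing
    already-normalized data is a no-op.
    """
    df = validate_dose_response(df.copy())
    if reference_ligand not in set(df["ligand"]):
        raise ValueError(f"reference ligand {reference_ligand!r} absent from data")
    for pathway, g in df.groupby("pathway"):
        ref = g[g["ligand"] == reference_ligand]
        if ref.empty:
            raise ValueError(f"reference ligand absent from pathway {pathway!r}")
        fit = fit_logistic(ref)[(reference_ligand, pathway)]
        if "degenerate_flat" in fit.flags:
            raise ValueError(f"reference ligand has no plateau in pathway {pathway!r}")
        span = fit.top - fit.bottom
        mask = df["pathway"] == pathway
        df.loc[mask, "response"] = (df.loc[mask, "response"] - fit.bottom) / span * 100.0
    return df


# ---------------------------------------------------------------------------
# Operational model
# ---------------------------------------------------------------------------

def operational_response(
    X: np.ndarray | float, logtau: float, logKA: float, n: float = 1.0, emax: float = 100.0
) -> np.ndarray | float:
    """Black–Leff operational-model response (% of system maximum)."""
    X = np.asarray(X, dtype=float)
    B = 10.0 ** (X * n) * 10.0 ** (logtau * n)
    Y = emax * B / (B + (10.0 ** X + 10.0 ** logKA) ** n)
    return float(Y) if Y.ndim == 0 else Y


@dataclass
class OperationalParams:
    """Fitted operational-model parameters for one ligand in one pathway."""

    ligand: str
    pathway: str
    logtau: float
    logKA: float
    n: float
    emax: float
    log_tau_ka: float  # transduction coefficient logτ − logK_A
    se_logtau: float
    se_logKA: float
    se_log_tau_ka: float  # from joint covariance of (logτ, logK_A)
    flags: list[str] = field(default_factory=list)

    @property
    def ec50(self) -> float:
        """Model EC50 in molar: K_A / ((2 + τ^n)^(1/n) − 1)."""
        tau_n = 10.0 ** (self.logtau * self.n)
        return 10.0 ** self.logKA / ((2.0 + tau_n) ** (1.0 / self.n) - 1.0)


def fit_operational(
    df: pd.DataFrame,
    shared_n: bool = True,
    emax: float = 100.0,
    logtau_max: float = 3.0,
) -> dict[str, OperationalParams]:
    """Global operational-model fit across all ligands of one pathway.

    The Hill slope n is shared across ligands (and Emax fixed, default 100);
    each ligand gets its own logτ and logK_A.  Standard errors come from the
    least-squares covariance; the transduction coefficient's SE uses the joint
    (logτ, logK_A) covariance.  ``df`` must contain a single pathway.
    """
    pathways = df["pathway"].unique()
    if len(pathways) != 1:
        raise ValueError("fit_operational expects data from exactly one pathway")
    pathway = str(pathways[0])
    ligands = sorted(df["ligand"].unique())
    tags = {lig: f"L{i}" for i, lig in enumerate(ligands)}

    x_all = df["log_conc_M"].to_numpy(dtype=float)
    y_all = df["response"].to_numpy(dtype=float)
    lig_idx = df["ligand"].map(tags).to_numpy()

    params = lmfit.Parameters()
    params.add("n", value=1.0, min=0.1, max=5.0, vary=shared_n)
    for lig in ligands:
        t = tags[lig]
        params.add(f"logtau_{t}", value=0.0, min=-3.0, max=logtau_max)
        params.add(f"logKA_{t}", value=float(np.median(x_all)), min=-15.0, max=0.0)

    def residual(p):
        n = p["n"].value
        out = np.empty_like(y_all)
        for lig in ligands:
            t = tags[lig]
            m = lig_idx == t
            out[m] = y_all[m] - operational_response(
                x_all[m], p[f"logtau_{t}"].value, p[f"logKA_{t}"].value, n, emax
            )
        return out

    mini = lmfit.Minimizer(residual, params)
    res = mini.minimize(method="leastsq", **_FIT_KWS)

    var_names = list(res.var_names)
    covar = res.covar
    out: dict[str, OperationalParams] = {}
    for lig in ligands:
        t = tags[lig]
        p_t, p_k = res.params[f"logtau_{t}"], res.params[f"logKA_{t}"]
        flags = []
        if not res.success:
            flags.append("fit_failed")
        if p_t.value > logtau_max - 0.1:
            flags.append("logtau_near_bound")  # full agonist: τ/K_A split not identifiable
        se_t = p_t.stderr if p_t.stderr is not None else np.nan
        se_k = p_k.stderr if p_k.stderr is not None else np.nan
        se_r = np.nan
        if covar is not None and f"logtau_{t}" in var_names and f"logKA_{t}" in var_names:
            i, j = var_names.index(f"logtau_{t}"), var_names.index(f"logKA_{t}")
            var_r = covar[i, i] + covar[j, j] - 2.0 * covar[i, j]
            se_r = float(np.sqrt(var_r)) if var_r >= 0 else np.nan
        out[lig] = OperationalParams(
            ligand=lig, pathway=pathway,
            logtau=float(p_t.value), logKA=float(p_k.value),
            n=float(res.params["n"].value), emax=emax,
            log_tau_ka=float(p_t.value - p_k.value),
            se_logtau=se_t, se_logKA=se_k, se_log_tau_ka=se_r, flags=flags,
        )
    return out


# ---------------------------------------------------------------------------
# Transduction coefficients, Δlog, ΔΔlog and bias factors
# ---------------------------------------------------------------------------

@dataclass
class TransductionCoefficient:
    ligand: str
    pathway: str
    value: float  # log(τ/K_A)
    se: float


@dataclass
class DeltaLog:
    ligand: str
    reference: str
    pathway: str
    value: float
    se: float


@dataclass
class DeltaDeltaLog:
    ligand: str
    reference: str
    pathway_order: tuple[str, str]
    value: float
    se: float


@dataclass
class BiasResult:
    ligand: str
    reference_ligand: str
    pathway_order: tuple[str, str]
    ddelta: float
    ddelta_se: float
    bias_factor: float
    ci_low: float | None
    ci_high: float | None
    level: float
    df: int | None
    warning: str | None = None


def transduction_coefficient(params: OperationalParams) -> TransductionCoefficient:
    """log(τ/K_A) with its joint-covariance standard error."""
    return TransductionCoefficient(
        params.ligand, params.pathway, params.log_tau_ka, params.se_log_tau_ka
    )


def delta_log(test: TransductionCoefficient, ref: TransductionCoefficient) -> DeltaLog:
    """Reference-normalized transduction coefficient within one pathway."""
    if test.pathway != ref.pathway:
        raise ValueError(
            f"pathway mismatch: {test.pathway!r} vs {ref.pathway!r}"
        )
    se = float(np.sqrt(np.nan_to_num(test.se) ** 2 + np.nan_to_num(ref.se) ** 2))
    return DeltaLog(test.ligand, ref.ligand, test.pathway, test.value - ref.value, se)


def ddelta_log(d_path1: DeltaLog, d_path2: DeltaLog) -> DeltaDeltaLog:
    """Between-pathway difference of Δlog(τ/K_A); antisymmetric in pathway order."""
    if d_path1.ligand != d_path2.ligand:
        raise ValueError(f"ligand mismatch: {d_path1.ligand!r} vs {d_path2.ligand!r}")
    se = float(np.sqrt(d_path1.se**2 + d_path2.se**2))
    return DeltaDeltaLog(
        d_path1.ligand, d_path1.reference,
        (d_path1.pathway, d_path2.pathway),
        d_path1.value - d_path2.value, se,
    )


def bias_factor(
    ddelta: DeltaDeltaLog, level: float = 0.95, df: int | None = None
) -> BiasResult:
    """Bias factor 10^ΔΔlog(τ/K_A) with a t-based CI symmetric in log10."""
    factor = 10.0 ** ddelta.value
    warning = None
    ci_low = ci_high = None
    if not np.isfinite(ddelta.se) or ddelta.se <= 0:
        warning = "non-positive or undefined SE; CI omitted"
    elif df is None or df < 1:
        warning = "no degrees of freedom supplied; CI omitted"
    else:
        t = stats.t.ppf(0.5 + level / 2.0, df)
        ci_low = 10.0 ** (ddelta.value - t * ddelta.se)
        ci_high = 10.0 ** (ddelta.value + t * ddelta.se)
    return BiasResult(
        ddelta.ligand, ddelta.reference, ddelta.pathway_order,
        ddelta.value, ddelta.se, factor, ci_low, ci_high, level, df, warning,
    )


def compute_bias(
    df: pd.DataFrame,
    reference_ligand: str,
    pathway_1: str,
    pathway_2: str,
    mode: str = "per_experiment",
    level: float = 0.95,
    shared_n: bool = True,
) -> dict[str, BiasResult]:
    """Full bias pipeline: operational fits → Δlog → ΔΔlog → bias factors.

    ``mode="per_experiment"`` (default) fits each replicate separately, forms
    Δlog per experiment, and averages across experiments with SE and df from
    the between-experiment scatter.  ``mode="global"`` uses one fit per
    pathway with SEs from the joint covariance.  ΔΔ is pathway_1 − pathway_2,
    so positive values mean bias toward pathway_1.
    """
    df = validate_dose_response(df)
    ligands = sorted(df["ligand"].unique())
    if reference_ligand not in ligands:
        raise ValueError(f"reference ligand {reference_ligand!r} absent")
    for pw in (pathway_1, pathway_2):
        if pw not in set(df["pathway"]):
            raise ValueError(f"pathway {pw!r} absent")

    if mode == "global":
        tc = {
            pw: {
                lig: transduction_coefficient(p)
                for lig, p in fit_operational(
                    df[df["pathway"] == pw], shared_n=shared_n
                ).items()
            }
            for pw in (pathway_1, pathway_2)
        }
        n_pts = len(df[df["pathway"].isin([pathway_1, pathway_2])])
        n_par = 2 * len(ligands) + 2  # per-pathway shared n + per-ligand (logτ, logK_A)
        dof = max(n_pts - n_par, 1)
        out = {}
        for lig in ligands:
            d1 = delta_log(tc[pathway_1][lig], tc[pathway_1][reference_ligand])
            d2 = delta_log(tc[pathway_2][lig], tc[pathway_2][reference_ligand])
            dd = ddelta_log(d1, d2)
            if lig == reference_ligand:
                dd = DeltaDeltaLog(lig, lig, dd.pathway_order, 0.0, 0.0)
            out[lig] = bias_factor(dd, level=level, df=dof)
        return out

    if mode != "per_experiment":
        raise ValueError(f"unknown mode {mode!r}")

    # Δlog per independent experiment (replicate), then averaged across them.
    dd_by_lig: dict[str, list[float]] = {lig: [] for lig in ligands}
    for rep, g in df.groupby("replicate"):
        deltas = {}
        ok = True
        for pw in (pathway_1, pathway_2):
            sub = g[g["pathway"] == pw]
            if sub.empty or reference_ligand not in set(sub["ligand"]):
                ok = False
                break
            fits = fit_operational(sub, shared_n=shared_n)
            ref_tc = transduction_coefficient(fits[reference_ligand])
            deltas[pw] = {
                lig: delta_log(transduction_coefficient(p), ref_tc).value
                for lig, p in fits.items()
            }
        if not ok:
            continue
        for lig in ligands:
            if lig in deltas[pathway_1] and lig in deltas[pathway_2]:
                dd_by_lig[lig].append(deltas[pathway_1][lig] - deltas[pathway_2][lig])

    out = {}
    for lig in ligands:
        vals = np.asarray(dd_by_lig[lig], dtype=float)
        if vals.size == 0:
            raise ValueError(f"no complete experiments for ligand {lig!r}")
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
        dof = int(vals.size - 1)
        if lig == reference_ligand:
            mean, se = 0.0, 0.0  # identically zero by construction
        dd = DeltaDeltaLog(lig, reference_ligand, (pathway_1, pathway_2), mean, se)
        out[lig] = bias_factor(dd, level=level, df=dof if dof >= 1 else None)
    return out


# ---------------------------------------------------------------------------
# Mutant potency fold changes
# ---------------------------------------------------------------------------

@dataclass
class FoldChange:
    fold: float
    rounded: int
    log10_fold: float


def potency_fold_change(ec50_variant: float, ec50_wt: float) -> FoldChange:
    """Potency loss of a receptor variant: EC50(variant) / EC50(wild type).

    Values above 1 mean the variant is less potent.  The rounded integer is
    the conventional reported figure; log10 fold feeds heatmaps.
    """
    if ec50_variant <= 0 or ec50_wt <= 0:
        raise ValueError("EC50 values must be positive")
    fold = ec50_variant / ec50_wt
    return FoldChange(fold, int(round(fold)), float(np.log10(fold)))


def fold_change_table(
    wt_ec50: Mapping[tuple[str, str], float],
    variant_ec50: Mapping[str, Mapping[tuple[str, str], float]],
) -> pd.DataFrame:
    """log10 potency-change matrix (variant × (ligand, pathway)) for heatmaps."""
    rows = {}
    for variant, table in variant_ec50.items():
        rows[variant] = {
            key: potency_fold_change(ec50, wt_ec50[key]).log10_fold
            for key, ec50 in table.items()
            if key in wt_ec50
        }
    return pd.DataFrame.from_dict(rows, orient="index")
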