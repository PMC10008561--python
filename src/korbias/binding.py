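"""Radioligand competition (one-site Ki) and dissociation-kinetics fitting.

Competition curves are fit with a fixed-slope (Hill = −1) logistic — the
one-site competition model — and the IC50 is converted to an inhibition
constant with the Cheng–Prusoff correction Ki = IC50 / (1 + L/Kd), where L is
the radioligand concentration and Kd its affinity.  Dissociation time courses
follow one-phase exponential decay Y(t) = (Y0 − NS)·exp(−koff·t) + NS with
half-life t½ = ln2/koff.  Surface-expression differences are removed by
normalizing counts to total protein (CPM/μg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

_FIT_KWS = dict(xtol=1e-13, ftol=1e-13, gtol=1e-13)


def cheng_prusoff(ic50: float, radioligand_conc: float, kd: float) -> float:
    """Ki from a competition IC50: Ki = IC50 / (1 + L/Kd)."""
    if ic50 <= 0 or radioligand_conc <= 0 or kd <= 0:
        raise ValueError("IC50, radioligand concentration and Kd must be positive")
    return ic50 / (1.0 + radioligand_conc / kd)


@dataclass
class KiFit:
    """One-site competition fit: logistic curve plus Cheng–Prusoff conversion."""

    log_ki: float
    se_log_ki: float
    log_ic50: float
    top: float
    bottom: float
    hill: float
    flags: list[str] = field(default_factory=list)

    @property
    def ki(self) -> float:
        return 10.0 ** self.log_ki


def _competition(x, top, bottom, logic50, hill):
    # hill < 0: descending with increasing log concentration
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((x - logic50) * -hill))


def fit_one_site_ki(
    df: pd.DataFrame,
    radioligand_conc: float,
    radioligand_kd: float,
    hill_fixed: float | None = -1.0,
) -> KiFit:
    """Fit a competition binding curve and report logKi ± SE.

    ``df`` needs columns ``log_conc_M`` and ``cpm``.  The Hill slope is fixed
    at −1 by default (one-site model); pass ``hill_fixed=None`` for a variable
    slope.  Flat data are returned flagged rather than raising.
    """
    x = df["log_conc_M"].to_numpy(dtype=float)
    y = df["cpm"].to_numpy(dtype=float)
    if df["log_conc_M"].nunique() < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.ptp(y) < 1e-9:
        return KiFit(np.nan, np.nan, np.nan, float(y.mean()), float(y.mean()),
                     hill_fixed or np.nan, ["degenerate_flat"])
    model = lmfit.Model(_competition)
    params = model.make_params(
        top=float(y.max()), bottom=float(y.min()),
        logic50=float(np.median(x)), hill=hill_fixed if hill_fixed is not None else -1.0,
    )
    if hill_fixed is not None:
        params["hill"].set(vary=False)
    else:
        params["hill"].set(min=-10.0, max=-0.1)
    res = model.fit(y, params, x=x, method="leastsq", fit_kws=_FIT_KWS)
    flags = [] if res.success else ["fit_failed"]
    p = res.params
    shift = np.log10(1.0 + radioligand_conc / radioligand_kd)
    se = p["logic50"].stderr if p["logic50"].stderr is not None else np.nan
    return KiFit(
        log_ki=float(p["logic50"].value - shift), se_log_ki=se,
        log_ic50=float(p["logic50"].value),
        top=float(p["top"].value), bottom=float(p["bottom"].value),
        hill=float(p["hill"].value), flags=flags,
    )


@dataclass
class KineticFit:
    """One-phase exponential dissociation fit."""

    y0: float
    ns: float  # nonspecific plateau
    koff: float  # min^-1
    t_half: float  # minutes, ln2/koff
    se_y0: float
    se_ns: float
    se_koff: float
    se_t_half: float
    flags: list[str] = field(default_factory=list)

    def predict(self, t: np.ndarray) -> np.ndarray:
        return (self.y0 - self.ns) * np.exp(-self.koff * np.asarray(t, dtype=float)) + self.ns


def _decay(t, y0, ns, koff):
    return (y0 - ns) * np.exp(-koff * t) + ns


def fit_dissociation(df: pd.DataFrame, ns_fixed: float | None = None) -> KineticFit:
    """Fit Y(t) = (Y0 − NS)·exp(−koff·t) + NS to a dissociation time course.

    ``df`` needs columns ``time_min`` and ``cpm``; time 0 is cold-ligand
    addition.  The nonspecific plateau NS is a free parameter unless supplied
    (e.g. from a blocker-defined value).  Fits with koff ≤ 0 or that fail to
    converge are returned flagged.
    """
    t = df["time_min"].to_numpy(dtype=float)
    y = df["cpm"].to_numpy(dtype=float)
    if df["time_min"].nunique() < 4:
        raise ValueError("need at least 4 distinct time points")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    model = lmfit.Model(_decay)
    span = max(np.ptp(y), 1e-9)
    koff0 = np.log(2.0) / max(np.median(t), 1e-6)
    params = model.make_params(
        y0=float(y[np.argmin(t)]), ns=float(y.min()), koff=koff0,
    )
    params["koff"].set(min=1e-9)
    if ns_fixed is not None:
        params["ns"].set(value=ns_fixed, vary=False)
    res = model.fit(y, params, t=t, method="leastsq", fit_kws=_FIT_KWS)
    p = res.params
    flags = []
    if not res.success:
        flags.append("fit_failed")
    koff = float(p["koff"].value)
    if koff <= 0:
        flags.append("nonpositive_koff")
    se_koff = p["koff"].stderr if p["koff"].stderr is not None else np.nan
    t_half = np.log(2.0) / koff if koff > 0 else np.nan
    se_t_half = (np.log(2.0) / koff**2) * se_koff if koff > 0 else np.nan
    return KineticFit(
        y0=float(p["y0"].value), ns=float(p["ns"].value), koff=koff, t_half=t_half,
        se_y0=p["y0"].stderr if p["y0"].stderr is not None else np.nan,
        se_ns=p["ns"].stderr if p["ns"].stderr is not None else np.nan,
        se_koff=se_koff, se_t_half=se_t_half, flags=flags,
    )


def normalize_expression(cpm: float, total_protein_ug: float) -> float:
    """Counts per μg total protein, removing expression-level differences."""
    if total_protein_ug <= 0:
        raise ValueError("total protein must be positive")
    return cpm / total_protein_ug
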