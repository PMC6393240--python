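"""Per-residue single-site binding isotherms fitted to CSP titration data.

For a labelled protein P titrated with ligand L under fast exchange, the
observed CSP of a reporter residue tracks the bound fraction.  With total
concentrations [P] and [L] and dissociation constant Kd, the bound fraction
follows the depletion-corrected (quadratic) single-site model

    f_b = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / (2 P)

and CSP(L) = csp_max * f_b.  When P << Kd this reduces to the hyperbolic
form csp_max * L / (L + Kd).  Per-residue (Kd, csp_max) are estimated by
least squares; a headline Kd is the unweighted mean over a set of
well-resolved reporter residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .csp_mapping import TitrationSeries, compute_csp, DEFAULT_NITROGEN_WEIGHT

__all__ = [
    "bound_fraction",
    "predict_csp",
    "ligand_schedule",
    "csp_vs_ligand",
    "fit_residue_kd",
    "fit_titration",
    "average_kd",
    "IsothermModel",
    "ResidueFit",
    "KdFitResult",
]

KD_UPPER_BOUND_UM = 1e5


def molar_ratio(conc_a: float, conc_b: float) -> float:
    """Molar ratio a:b of two concentrations given in the same units
    (e.g. 1.5 uM protein over 3 nM DNA expressed in M gives 500)."""
    if conc_a <= 0 or conc_b <= 0:
        raise ValueError("concentrations must be > 0")
    return conc_a / conc_b


def bound_fraction(P, L, Kd):
    """Fraction of labelled protein bound, quadratic single-site model."""
    P = np.asarray(P, dtype=float)
    L = np.asarray(L, dtype=float)
    s = P + L + Kd
    disc = s * s - 4.0 * P * L
    # disc >= (P - L)^2 + Kd^2 >= 0 analytically; clip guards rounding.
    # (s - sqrt(disc)) / 2P is rewritten as 2L / (s + sqrt(disc)) to avoid
    # catastrophic cancellation when Kd >> P, L.
    fb = 2.0 * L / (s + np.sqrt(np.clip(disc, 0.0, None)))
    return fb if fb.ndim else float(fb)


def predict_csp(L, P: float, Kd: float, csp_max: float, model: str = "quadratic"):
    """Forward isotherm: CSP at total ligand concentration L (uM)."""
    if model == "quadratic":
        return csp_max * bound_fraction(P, L, Kd)
    if model == "hyperbolic":
        L = np.asarray(L, dtype=float)
        out = csp_max * L / (L + Kd)
        return out if out.ndim else float(out)
    raise ValueError(f"unknown isotherm model {model!r}")


@dataclass
class IsothermModel:
    """A concrete single-site isotherm for one residue."""

    Kd: float  # uM
    csp_max: float  # ppm
    P: float  # labelled protein, uM
    model: str = "quadratic"

    def __post_init__(self) -> None:
        if self.Kd <= 0 or self.csp_max <= 0 or self.P <= 0:
            raise ValueError("Kd, csp_max and P must all be > 0")

    def predict(self, L):
        return predict_csp(L, self.P, self.Kd, self.csp_max, self.model)


def ligand_schedule(series: TitrationSeries) -> np.ndarray:
    """Total ligand concentrations (uM): molar ratio x labelled protein."""
    return series.ratios * series.labelled_protein_concentration


def csp_vs_ligand(
    series: TitrationSeries,
    residue: int,
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
    convention: str = "scaled_squared",
) -> tuple[np.ndarray, np.ndarray]:
    """(L, CSP) arrays for one residue across every titration point where it
    is observed; CSPs are vs the apo reference."""
    ref = series.reference.indexed()
    if residue not in ref.index:
        raise KeyError(f"residue {residue} absent from the reference peak list")
    L_all = ligand_schedule(series)
    Ls, csps = [], []
    for (ratio, peaks), L in zip(series.points, L_all):
        pk = peaks.indexed()
        if residue not in pk.index:
            continue
        csp = compute_csp(
            pk.loc[residue, "dH_ppm"] - ref.loc[residue, "dH_ppm"],
            pk.loc[residue, "dN_ppm"] - ref.loc[residue, "dN_ppm"],
            nitrogen_weight=nitrogen_weight,
            convention=convention,
        )
        Ls.append(L)
        csps.append(csp)
    return np.asarray(Ls), np.asarray(csps)


@dataclass
class ResidueFit:
    residue: int
    Kd: float
    csp_max: float
    Kd_stderr: float | None
    csp_max_stderr: float | None
    residual_norm: float
    converged: bool
    n_points: int


@dataclass
class KdFitResult:
    per_residue: dict[int, ResidueFit]
    averaged_Kd: float | None = None
    averaged_sd: float | None = None
    averaged_stderr: float | None = None  # mean of per-fit standard errors
    residues_used: list[int] = field(default_factory=list)
    P: float | None = None

    def to_dict(self) -> dict:
        return {
            "averaged_Kd_uM": self.averaged_Kd,
            "averaged_sd_uM": self.averaged_sd,
            "averaged_stderr_uM": self.averaged_stderr,
            "residues_used": self.residues_used,
            "labelled_protein_uM": self.P,
            "per_residue": {
                str(r): {
                    "Kd_uM": f.Kd,
                    "csp_max_ppm": f.csp_max,
                    "Kd_stderr_uM": f.Kd_stderr,
                    "csp_max_stderr_ppm": f.csp_max_stderr,
                    "residual_norm": f.residual_norm,
                    "converged": f.converged,
                    "n_points": f.n_points,
                }
                for r, f in sorted(self.per_residue.items())
            },
        }


def _shared_reference_stderr(
    L: np.ndarray, csp: np.ndarray, P: float, kd: float, cmax: float, model: str
) -> tuple[float | None, float | None]:
    """Sandwich standard errors for (Kd, csp_max) under shared-reference
    noise: errors carry an independent per-point part plus a component
    common to every non-zero-L point (the apo reference spectrum's noise),
    both with the residual variance.  The L = 0 point is exact by
    construction (CSP against itself)."""
    theta = np.array([kd, cmax])

    def predict(th):
        return predict_csp(L, P, th[0], th[1], model)

    J = np.empty((L.size, 2))
    for j in range(2):
        h = 1e-6 * max(abs(theta[j]), 1e-9)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (predict(tp) - predict(tm)) / (2 * h)
    resid = csp - predict(theta)
    n, p = L.size, 2
    if n <= p:
        return None, None
    s2 = float(resid @ resid) / (n - p)
    nz = L > 0
    Sigma = np.zeros((n, n))
    Sigma[np.ix_(nz, nz)] = s2  # common reference-noise block
    Sigma[np.diag_indices(n)] += s2 * nz  # independent per-point part
    try:
        bread = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return None, None
    cov = bread @ J.T @ Sigma @ J @ bread
    return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))


def fit_residue_kd(
    L,
    csp,
    P: float,
    model: str = "quadratic",
    residue: int = -1,
    max_rel_stderr: float = 1.0,
) -> ResidueFit:
    """Least-squares (Kd, csp_max) for one residue's isotherm.

    Starting values: Kd0 = midpoint of the ligand schedule, csp_max0 =
    1.2x the largest observed CSP; Kd bounded in (0, 1e5 uM].  Requires at
    least 4 points including the L = 0 reference.

    A fit only counts as converged (hence enters Kd averaging) when it is
    *well resolved*: the optimiser succeeded, a Kd standard error could be
    estimated, and that error does not exceed ``max_rel_stderr`` times the
    estimate.  Runaway fits on weakly saturating data are thereby flagged
    rather than polluting the averaged Kd.

    Reported standard errors use a sandwich covariance that models the
    error correlation induced by the shared apo reference spectrum: every
    CSP in a titration is measured against the same noisy reference, so
    plain least-squares errors (which assume independent residuals)
    underestimate the uncertainty.
    """
    L = np.asarray(L, dtype=float)
    csp = np.asarray(csp, dtype=float)
    if L.size != csp.size:
        raise ValueError("L and CSP arrays differ in length")
    if L.size < 4:
        raise ValueError("need at least 4 titration points to fit Kd")
    if not np.any(L == 0):
        raise ValueError("fit requires the L = 0 reference point")
    if not np.all(np.isfinite(csp)):
        raise ValueError("non-finite CSP values")
    if np.all(csp == 0):
        raise ValueError("no binding signal: all CSPs are zero")

    def isotherm(L, Kd, csp_max):
        return predict_csp(L, P, Kd, csp_max, model)

    lm = Model(isotherm)
    params = lm.make_params(
        Kd={"value": 0.5 * (L.min() + L.max()), "min": 1e-9, "max": KD_UPPER_BOUND_UM},
        csp_max={"value": 1.2 * float(csp.max()), "min": 1e-12},
    )
    try:
        res = lm.fit(csp, params, L=L)
        converged = bool(res.success)
    except Exception:
        res = None
        converged = False

    if res is None:
        return ResidueFit(residue, np.nan, np.nan, None, None, np.inf, False, L.size)

    kd = float(res.params["Kd"].value)
    cmax = float(res.params["csp_max"].value)
    kd_err, cmax_err = _shared_reference_stderr(L, csp, P, kd, cmax, model)
    if kd_err is None:  # fall back to the plain least-squares errors
        kd_err = res.params["Kd"].stderr
        cmax_err = res.params["csp_max"].stderr
    if kd_err is None or not np.isfinite(kd_err) or kd_err > max_rel_stderr * kd:
        converged = False
    return ResidueFit(
        residue=residue,
        Kd=kd,
        csp_max=cmax,
        Kd_stderr=float(kd_err) if kd_err is not None else None,
        csp_max_stderr=float(cmax_err) if cmax_err is not None else None,
        residual_norm=float(np.linalg.norm(res.residual)),
        converged=converged,
        n_points=int(L.size),
    )


def fit_titration(
    series: TitrationSeries,
    residues,
    model: str = "quadratic",
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
    convention: str = "scaled_squared",
) -> KdFitResult:
    """Fit every requested residue and average the converged Kds."""
    P = series.labelled_protein_concentration
    fits: dict[int, ResidueFit] = {}
    for residue in residues:
        L, csp = csp_vs_ligand(series, residue, nitrogen_weight, convention)
        fits[residue] = fit_residue_kd(L, csp, P, model=model, residue=residue)
    result = KdFitResult(per_residue=fits, P=P)
    converged = [r for r, f in fits.items() if f.converged]
    if converged:
        mean, sd = average_kd(result, converged)
        result.averaged_Kd = mean
        result.averaged_sd = sd
        result.residues_used = sorted(converged)
        errs = [fits[r].Kd_stderr for r in converged if fits[r].Kd_stderr is not None]
        result.averaged_stderr = float(np.mean(errs)) if errs else None
    return result


def average_kd(
    result: KdFitResult,
    residues,
    sd_estimator: str = "sample",
    weighting: str = "unweighted",
) -> tuple[float, float]:
    """Mean +/- sd of Kd over a named residue set.

    The default is the unweighted mean with the sample (n-1) standard
    deviation; ``weighting='inverse_variance'`` uses the per-fit standard
    errors instead.  Every named residue must have a converged fit.
    """
    residues = list(residues)
    missing = [r for r in residues if r not in result.per_residue]
    bad = [r for r in residues if r in result.per_residue and not result.per_residue[r].converged]
    if missing or bad:
        raise ValueError(
            f"cannot average Kd: missing residues {missing}, non-converged {bad}"
        )
    kds = np.array([result.per_residue[r].Kd for r in residues], dtype=float)
    if weighting == "inverse_variance":
        errs = np.array(
            [result.per_residue[r].Kd_stderr or np.nan for r in residues], dtype=float
        )
        if np.any(~np.isfinite(errs)) or np.any(errs <= 0):
            raise ValueError("inverse-variance weighting needs finite positive stderrs")
        w = 1.0 / errs**2
        mean = float(np.sum(w * kds) / np.sum(w))
    else:
        mean = float(kds.mean())
    if kds.size == 1:
        return mean, 0.0
    ddof = 1 if sd_estimator == "sample" else 0
    return mean, float(kds.std(ddof=ddof))
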