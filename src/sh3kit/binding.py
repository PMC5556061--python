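"""Binding-readout models: one-site ITC isotherms and 4PL displacement.

The ITC forward model tracks cell concentrations through a perfusion
(displaced-volume) injection series: each injection is mixed into the
full cell + injection volume, the 1:1 quadratic binding equilibrium is
solved, the measured heat covers complex formed in that mixed volume,
and the overflow volume then leaves the cell.  Simulator and fitter
share this forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares


class BindingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameters and fixtures


@dataclass(frozen=True)
class BindingParams:
    """One-site binding truth: Kd (uM), enthalpy (kcal/mol), stoichiometry."""

    kd: float
    dh: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise BindingError("kd must be positive")
        if self.n <= 0:
            raise BindingError("stoichiometry must be positive")


@dataclass(frozen=True)
class FourPLParams:
    """Four-parameter logistic truth/fit: EC50 in dose units."""

    ec50: float
    top: float = 1.0
    bottom: float = 0.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise BindingError("ec50 must be positive")
        if self.top < self.bottom:
            raise BindingError("top must be >= bottom")

    def response(self, doses: np.ndarray) -> np.ndarray:
        doses = np.asarray(doses, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (doses / self.ec50) ** self.hill
        )


#: Ground-truth registry for synthetic fixtures.  Kd values follow the
#: measured dissociation constants of the four octapeptides; enthalpies
#: are plausible exothermic values (not measured quantities).
PEPTIDE_BINDING_TRUTH: Dict[str, BindingParams] = {
    "PPPKPPRL": BindingParams(kd=5.29, dh=-8.2, n=1.0),
    "APPKPPLP": BindingParams(kd=15.70, dh=-7.6, n=1.0),
    "PPSKPPRP": BindingParams(kd=15.29, dh=-7.9, n=1.0),
    "PPSKPPLP": BindingParams(kd=46.65, dh=-7.1, n=1.0),
}

#: Displacement-assay truth for the tightest phage clone: EC50 363 nM.
CLONE1_EC50_NM = 363.0
#: Molar mass used to convert ug/ml competitor doses to nM (GST-fused
#: SH3 domain, ~34 kDa).
COMPETITOR_MASS_KDA = 34.0


def clone1_displacement_truth() -> FourPLParams:
    return FourPLParams(ec50=CLONE1_EC50_NM, top=1.0, bottom=0.0, hill=1.0)


def ug_per_ml_to_nm(dose_ug_ml, mass_kda: float = COMPETITOR_MASS_KDA):
    """ug/ml -> nM for a competitor of the given molar mass."""
    return np.asarray(dose_ug_ml, dtype=float) / mass_kda * 1000.0


# ---------------------------------------------------------------------------
# ITC


@dataclass(frozen=True)
class TitrationSchedule:
    cell_volume: float = 200.0    # ul
    cell_conc: float = 60.0       # uM protein in cell
    syringe_conc: float = 660.0   # uM titrant
    injection_volume: float = 2.0  # ul
    n_injections: int = 19

    def __post_init__(self) -> None:
        for name in ("cell_volume", "cell_conc", "syringe_conc",
                     "injection_volume"):
            if getattr(self, name) <= 0:
                raise BindingError(f"{name} must be positive")
        if self.n_injections < 1:
            raise BindingError("need at least one injection")


@dataclass
class Titration:
    heats: np.ndarray            # ucal per injection
    schedule: TitrationSchedule
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def to_tsv(self, path) -> None:
        lines = ["injection\theat_ucal"]
        for i, q in enumerate(self.heats, start=1):
            lines.append(f"{i}\t{q:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path, schedule: Optional[TitrationSchedule] = None):
        lines = Path(path).read_text().strip().splitlines()
        heats = np.array([float(l.split("\t")[1]) for l in lines[1:]])
        return cls(heats=heats, schedule=schedule or TitrationSchedule(
            n_injections=len(heats)))


def _binding_polynomial(total_sites: float, total_ligand: float,
                        kd: float) -> float:
    """Equilibrium complex concentration for 1:1 binding (uM inputs)."""
    b = total_sites + total_ligand + kd
    disc = b * b - 4.0 * total_sites * total_ligand
    return 0.5 * (b - math.sqrt(max(disc, 0.0)))


def itc_heats(
    params: BindingParams,
    schedule: TitrationSchedule,
    baseline: float = 0.0,
) -> np.ndarray:
    """Noise-free heats (ucal) for each injection of the schedule."""
    v0 = schedule.cell_volume
    dv = schedule.injection_volume
    m = schedule.cell_conc     # uM protein in cell
    x = 0.0                    # uM titrant in cell
    ml_prev = 0.0              # uM complex in cell
    heats = np.empty(schedule.n_injections)
    for i in range(schedule.n_injections):
        f = v0 / (v0 + dv)
        m *= f
        x = x * f + schedule.syringe_conc * dv / (v0 + dv)
        ml = _binding_polynomial(params.n * m, x, params.kd)
        # heat covers complex formed in the mixed (cell + injection) volume
        q = params.dh * (ml * (v0 + dv) - ml_prev * v0) * 1e-3  # ucal
        heats[i] = q + baseline
        ml_prev = ml
    return heats


def simulate_itc(
    params: BindingParams,
    schedule: Optional[TitrationSchedule] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Titration:
    """Forward-simulate a titration with optional Gaussian heat noise."""
    schedule = schedule or TitrationSchedule()
    heats = itc_heats(params, schedule)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=len(heats))
    return Titration(heats=heats, schedule=schedule, noise_sd=noise_sd,
                     seed=seed)


@dataclass
class BindingFit:
    kd: float
    dh: float
    n: float
    baseline: float
    kd_variance: float
    covariance: np.ndarray      # over (log10 kd, dh, n, baseline)
    rss: float
    c_value: float
    converged: bool = True
    flag: Optional[str] = None


_KD_MULTISTART = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)  # uM


def fit_one_site(titration: Titration) -> BindingFit:
    """Nonlinear least squares for (Kd, dH, N, baseline) with multistart.

    Kd is fitted in log10 space for conditioning; non-convergence or an
    unidentifiable titration returns a flagged fit rather than raising.
    """
    heats = np.asarray(titration.heats, dtype=float)
    schedule = titration.schedule
    if len(heats) < 6:
        raise BindingError("need at least 6 injections to fit")

    scale = float(np.max(np.abs(heats)))
    if scale == 0.0 or not np.isfinite(scale):
        return BindingFit(
            kd=math.nan, dh=math.nan, n=math.nan, baseline=0.0,
            kd_variance=math.inf, covariance=np.full((4, 4), np.nan),
            rss=0.0, c_value=math.nan, converged=False,
            flag="unidentifiable: all heats zero",
        )

    dh0 = float(np.sum(heats) * 1e-3 /
                (schedule.cell_conc * schedule.cell_volume * 1e-3))
    if dh0 == 0.0:
        dh0 = -1.0

    def residuals(theta: np.ndarray) -> np.ndarray:
        lkd, dh, n, base = theta
        model = itc_heats(
            BindingParams(kd=10.0 ** lkd, dh=dh, n=max(n, 1e-6)),
            schedule, baseline=base,
        )
        return model - heats

    best = None
    for kd0 in _KD_MULTISTART:
        theta0 = np.array([math.log10(kd0), dh0, 1.0, 0.0])
        try:
            res = least_squares(
                residuals, theta0,
                bounds=([-4.0, -np.inf, 1e-3, -np.inf],
                        [5.0, np.inf, 10.0, np.inf]),
                method="trf", xtol=1e-12, ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return BindingFit(
            kd=math.nan, dh=math.nan, n=math.nan, baseline=0.0,
            kd_variance=math.inf, covariance=np.full((4, 4), np.nan),
            rss=math.nan, c_value=math.nan, converged=False,
            flag="no multistart converged",
        )

    lkd, dh, n, base = best.x
    kd = 10.0 ** lkd
    rss = 2.0 * best.cost
    dof = max(len(heats) - 4, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * rss / dof
    kd_var = (kd * math.log(10.0)) ** 2 * cov[0, 0]
    c_value = n * schedule.cell_conc / kd
    return BindingFit(
        kd=kd, dh=dh, n=n, baseline=base,
        kd_variance=float(kd_var), covariance=cov, rss=float(rss),
        c_value=float(c_value), converged=True,
    )


def fit_one_site_global(titrations: Sequence[Titration]) -> BindingFit:
    """Joint maximum-likelihood fit of replicate titrations.

    All replicates share (Kd, dH, N); each keeps its own baseline.  This
    is the proper pooled ML estimator for identically designed replicate
    experiments and is markedly less biased than inverse-variance
    averaging of per-replicate estimates, whose variance estimates
    correlate with the estimates themselves.
    """
    if len(titrations) < 2:
        raise BindingError("need at least 2 replicates for a global fit")
    schedule = titrations[0].schedule
    heats = [np.asarray(t.heats, dtype=float) for t in titrations]
    n_rep = len(heats)

    def residuals(theta: np.ndarray) -> np.ndarray:
        lkd, dh, n = theta[:3]
        base = theta[3:]
        model = itc_heats(
            BindingParams(kd=10.0 ** lkd, dh=dh, n=max(n, 1e-6)), schedule
        )
        return np.concatenate(
            [model + base[r] - heats[r] for r in range(n_rep)]
        )

    dh0 = float(np.mean([h.sum() for h in heats]) * 1e-3 /
                (schedule.cell_conc * schedule.cell_volume * 1e-3)) or -1.0
    lower = np.concatenate([[-4.0, -np.inf, 1e-3],
                            np.full(n_rep, -np.inf)])
    upper = np.concatenate([[5.0, np.inf, 10.0], np.full(n_rep, np.inf)])
    best = None
    for kd0 in (0.1, 1.0, 10.0, 100.0):
        theta0 = np.concatenate(
            [[math.log10(kd0), dh0, 1.0], np.zeros(n_rep)]
        )
        try:
            res = least_squares(residuals, theta0, bounds=(lower, upper),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return BindingFit(
            kd=math.nan, dh=math.nan, n=math.nan, baseline=0.0,
            kd_variance=math.inf, covariance=np.full((4, 4), np.nan),
            rss=math.nan, c_value=math.nan, converged=False,
            flag="global fit did not converge",
        )
    lkd, dh, n = best.x[:3]
    kd = 10.0 ** lkd
    rss = 2.0 * best.cost
    dof = max(sum(len(h) for h in heats) - len(best.x), 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * rss / dof
    kd_var = (kd * math.log(10.0)) ** 2 * cov[0, 0]
    return BindingFit(
        kd=kd, dh=float(dh), n=float(n),
        baseline=float(np.mean(best.x[3:])),
        kd_variance=float(kd_var), covariance=cov[:4, :4], rss=float(rss),
        c_value=float(n * schedule.cell_conc / kd), converged=True,
    )


def pool_estimates(
    values: Sequence[float], variances: Sequence[float]
) -> Tuple[float, float]:
    """Inverse-variance weighted mean and pooled variance 1/sum(1/var).

    Infinite-variance replicates are dropped (with at least one finite
    required); a zero variance makes that replicate dominate.
    """
    vals = np.asarray(values, dtype=float)
    var = np.asarray(variances, dtype=float)
    finite = np.isfinite(var) & np.isfinite(vals)
    if not finite.any():
        raise BindingError("no replicate with finite variance")
    vals, var = vals[finite], var[finite]
    if np.any(var == 0.0):
        exact = vals[var == 0.0]
        return float(exact.mean()), 0.0
    weights = 1.0 / var
    pooled_var = 1.0 / weights.sum()
    return float((weights * vals).sum() * pooled_var), float(pooled_var)


def pool_kd(fits: Sequence[BindingFit]) -> Tuple[float, float]:
    """Pooled Kd +/- sd from replicate fits (inverse-variance weighting)."""
    good = [f for f in fits if f.converged]
    if len(good) < 2:
        raise BindingError("need at least 2 converged fits to pool")
    value, var = pool_estimates(
        [f.kd for f in good], [f.kd_variance for f in good]
    )
    return value, math.sqrt(var)


def pool_stoichiometry(fits: Sequence[BindingFit]) -> Tuple[float, float]:
    good = [f for f in fits if f.converged]
    if len(good) < 2:
        raise BindingError("need at least 2 converged fits to pool")
    variances = []
    for f in good:
        variances.append(float(f.covariance[2, 2]))
    value, var = pool_estimates([f.n for f in good], variances)
    return value, math.sqrt(var)


# ---------------------------------------------------------------------------
# 4PL displacement


@dataclass
class DoseResponse:
    doses: np.ndarray
    responses: np.ndarray
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if len(self.doses) != len(self.responses):
            raise BindingError("doses and responses must align")
        if np.any(np.diff(self.doses) <= 0):
            raise BindingError("doses must be strictly increasing")

    def to_tsv(self, path) -> None:
        lines = ["dose\tresponse"]
        for d, r in zip(self.doses, self.responses):
            lines.append(f"{d:.8g}\t{r:.8g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path):
        lines = Path(path).read_text().strip().splitlines()
        pairs = [tuple(map(float, l.split("\t"))) for l in lines[1:]]
        return cls(doses=np.array([p[0] for p in pairs]),
                   responses=np.array([p[1] for p in pairs]))


def simulate_displacement(
    truth: FourPLParams,
    doses: np.ndarray,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> DoseResponse:
    """y = bottom + (top - bottom) / (1 + (x/ec50)^hill) + noise."""
    doses = np.asarray(doses, dtype=float)
    responses = truth.response(doses)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        responses = responses + rng.normal(0.0, noise_sd, size=len(doses))
    return DoseResponse(doses=doses, responses=responses, noise_sd=noise_sd,
                        seed=seed)


@dataclass
class FourPLFit:
    ec50: float
    top: float
    bottom: float
    hill: float
    covariance: np.ndarray  # over (log10 ec50, top, bottom, hill)
    ec50_variance: float
    rss: float
    converged: bool = True
    flag: Optional[str] = None

    @property
    def params(self) -> FourPLParams:
        return FourPLParams(ec50=self.ec50, top=max(self.top, self.bottom),
                            bottom=self.bottom, hill=self.hill)


def fit_4pl(curve: DoseResponse) -> FourPLFit:
    """Least-squares four-parameter logistic fit; EC50 in input dose units."""
    doses = curve.doses
    y = curve.responses
    if len(doses) < 5:
        raise BindingError("need at least 5 doses to fit a 4PL")
    span = float(y.max() - y.min())
    if span == 0.0:
        return FourPLFit(
            ec50=math.nan, top=float(y[0]), bottom=float(y[0]), hill=math.nan,
            covariance=np.full((4, 4), np.nan), ec50_variance=math.inf,
            rss=0.0, converged=False, flag="flat data",
        )

    def residuals(theta):
        lec, top, bottom, hill = theta
        with np.errstate(over="ignore"):
            model = bottom + (top - bottom) / (
                1.0 + (doses / 10.0 ** lec) ** hill
            )
        return model - y

    mid = 0.5 * (y.max() + y.min())
    ec0 = float(doses[np.argmin(np.abs(y - mid))])
    theta0 = np.array([math.log10(ec0), float(y.max()), float(y.min()), 1.0])
    best = None
    for lec0 in (theta0[0] - 1, theta0[0], theta0[0] + 1):
        start = theta0.copy()
        start[0] = lec0
        res = least_squares(residuals, start, method="lm",
                            xtol=1e-14, ftol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    lec, top, bottom, hill = best.x
    ec50 = 10.0 ** lec
    rss = 2.0 * best.cost
    dof = max(len(doses) - 4, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * rss / dof
    ec_var = (ec50 * math.log(10.0)) ** 2 * cov[0, 0]

    flag = None
    if ec50 < doses.min() / 10 or ec50 > doses.max() * 10:
        flag = "ec50 outside sampled dose range; unidentifiable"
    elif abs(top - bottom) < 3.0 * math.sqrt(rss / dof):
        flag = "dynamic range indistinguishable from noise; unidentifiable"
    return FourPLFit(
        ec50=ec50, top=float(top), bottom=float(bottom), hill=float(hill),
        covariance=cov, ec50_variance=float(ec_var), rss=float(rss),
        converged=flag is None, flag=flag,
    )


def relative_affinity(
    curves: Mapping[str, DoseResponse], reference_label: str
) -> Dict[str, float]:
    """Half-saturation-dose ratios relative to the reference clone.

    ratio = midpoint dose of reference / midpoint dose of clone, so the
    reference maps to 1 and weaker binders to values < 1.  Unfittable
    curves are excluded with a warning.
    """
    import warnings

    if reference_label not in curves:
        raise BindingError(f"reference {reference_label!r} not among curves")
    fits: Dict[str, FourPLFit] = {}
    for label, curve in curves.items():
        fit = fit_4pl(curve)
        if not fit.converged:
            warnings.warn(f"curve {label!r} unfittable ({fit.flag}); excluded")
            continue
        fits[label] = fit
    if reference_label not in fits:
        raise BindingError("reference curve could not be fitted")
    ref = fits[reference_label].ec50
    return {label: ref / fit.ec50 for label, fit in fits.items()}
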