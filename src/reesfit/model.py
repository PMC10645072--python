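"""Two-state sigmoidal thermodynamic model of the red edge excitation shift.

The centre of spectral mass as a function of excitation wavelength is
modelled as a Boltzmann-weighted average of emission from two states:
the fully excited Franck-Condon state (CSM(lambda_Ex,FC), the blue
asymptote) and the fully solvent-relaxed state (CSM(lambda_Ex,R), the
red asymptote),

    CSM(lx) = [CSM_FC + CSM_R * exp(x)] / [1 + exp(x)],
    x = m * (lx - lx50) / (R * T),

where lx50 is the inflection excitation wavelength (CSM halfway between
the asymptotes) and m is the slope term with units J mol^-1 nm^-1,
interpreted as the change in Gibbs free energy per nm of excitation
(reported in results tables as "Delta G_m").  Higher CSM_FC indicates a
more solvent-exposed tryptophan ensemble; higher m indicates greater
structural rigidity.

The relaxed-state CSM cannot be observed directly (there is not enough
lamp intensity beyond ~310 nm), so it is only weakly identified by any
single profile.  Two fitting modes are provided:

* :func:`fit_single` - all four parameters free for one profile, with
  CSM_R bound-constrained to [387, 440] nm;
* :func:`fit_group_global` - one shared CSM_R for every replicate of
  every sample in a group, with per-replicate (CSM_FC, m, lx50), which
  is the recommended mode and mirrors how groups of closely related
  proteins with equal tryptophan content should share a relaxed state.

Note on units: results tables in the field sometimes print Delta G_m
with an ambiguous milli- prefix; the fit here is carried out entirely in
J mol^-1 nm^-1 (the unit in which x = m * dlx / RT is dimensionless) and
``m_display_scale`` in :class:`FitOptions` only rescales reported
values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .csm import CSMProfile

__all__ = [
    "REESConstants",
    "REESParams",
    "FitOptions",
    "FitDiagnostics",
    "ReplicateFit",
    "GroupFitResult",
    "model_csm",
    "initialize_params",
    "fit_single",
    "fit_group_global",
    "summarize_table",
]

CSM_R_BOUNDS = (387.0, 440.0)


@dataclass(frozen=True)
class REESConstants:
    """Physical constants of the Boltzmann factor."""

    R: float = 8.3145  # gas constant, J mol^-1 K^-1
    T: float = 283.15  # temperature, K

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.R <= 0:
            raise ValueError("gas constant must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass(frozen=True)
class REESParams:
    """Parameters of the two-state sigmoid.

    csm_fc, csm_r and lambda50 are in nm; m is in J mol^-1 nm^-1.
    """

    csm_fc: float
    m: float
    lambda50: float
    csm_r: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.csm_fc, self.m, self.lambda50, self.csm_r]).all():
            raise ValueError("REES parameters must be finite")
        if self.csm_fc >= self.csm_r:
            raise ValueError(
                f"csm_fc ({self.csm_fc:g}) must be below csm_r ({self.csm_r:g}): "
                "the red edge shifts emission to longer wavelengths"
            )
        if self.m <= 0:
            raise ValueError("slope m must be positive")


def model_csm(lambda_ex, params: REESParams, constants: REESConstants = REESConstants()):
    """Evaluate the sigmoid at one or many excitation wavelengths.

    Overflow-safe for arbitrarily large |x| via the logistic function:
    CSM = csm_fc + (csm_r - csm_fc) * sigmoid(x).
    """
    lx = np.asarray(lambda_ex, dtype=float)
    x = params.m * (lx - params.lambda50) / constants.RT
    out = params.csm_fc + (params.csm_r - params.csm_fc) * expit(x)
    return float(out) if np.isscalar(lambda_ex) else out


@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration for single and global fits."""

    csm_r_bounds: tuple[float, float] = CSM_R_BOUNDS
    ftol: float = 1e-10
    xtol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: int | None = None
    n_starts: int = 5  # deterministic perturbations of the initial guess
    share_csm_r: str = "replicates"  # or "sample_means"
    m_display_scale: float = 1.0  # multiplies m in report tables only

    def __post_init__(self) -> None:
        lo, hi = self.csm_r_bounds
        if not lo < hi:
            raise ValueError("csm_r bounds must satisfy lo < hi")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.share_csm_r not in ("replicates", "sample_means"):
            raise ValueError("share_csm_r must be 'replicates' or 'sample_means'")


@dataclass(frozen=True)
class FitDiagnostics:
    converged: bool
    identifiable: bool
    n_evaluations: int
    objective: float  # sum of squared residuals
    message: str = ""


@dataclass(frozen=True)
class ReplicateFit:
    sample_id: str
    replicate_index: int
    params: REESParams
    residual_norm: float


@dataclass(frozen=True)
class GroupFitResult:
    group_label: str
    shared_csm_r: float
    shared_csm_r_se: float
    per_replicate: tuple[ReplicateFit, ...]
    per_sample_summary: pd.DataFrame  # index sample_id; mean/sd per parameter
    diagnostics: FitDiagnostics


# in parameter-vector order (csm_fc, m, lambda50): loose stabilising bounds
_LOCAL_LO = np.array([250.0, 1e-9, 200.0])
_LOCAL_HI = np.array([500.0, 1e6, 600.0])


def initialize_params(
    profile: CSMProfile, constants: REESConstants = REESConstants()
) -> REESParams:
    """Deterministic initial guess.

    The blue asymptote starts at the CSM observed at the shortest
    excitation; the relaxed state at the midpoint of its allowed range;
    the inflection 10 nm beyond the measured excitations (it is not
    reachable experimentally); m at RT/5, i.e. a 5 nm characteristic
    transition width.
    """
    if len(profile) < 4:
        raise ValueError(
            f"profile has {len(profile)} points; at least 4 are required "
            "(four free parameters)"
        )
    return REESParams(
        csm_fc=float(profile.csm[0]),
        m=constants.RT / 5.0,
        lambda50=float(profile.excitation_wavelengths[-1] + 10.0),
        csm_r=0.5 * (CSM_R_BOUNDS[0] + CSM_R_BOUNDS[1]),
    )


def _sigmoid_terms(theta_local, csm_r, lx, RT):
    csm_fc, m, lx50 = theta_local
    x = m * (lx - lx50) / RT
    s = expit(x)
    return csm_fc + (csm_r - csm_fc) * s, s, x


def _local_jacobian(theta_local, csm_r, lx, RT):
    """d(model)/d(csm_fc, m, lambda50, csm_r) as four columns."""
    csm_fc, m, lx50 = theta_local
    x = m * (lx - lx50) / RT
    s = expit(x)
    ds = s * (1.0 - s)
    diff = csm_r - csm_fc
    return np.column_stack(
        [
            1.0 - s,  # d/d csm_fc
            diff * ds * (lx - lx50) / RT,  # d/d m
            -diff * ds * m / RT,  # d/d lambda50
            s,  # d/d csm_r
        ]
    )


def _start_variants(init: REESParams, options: FitOptions, n_max: int):
    """Deterministic multi-start perturbations; the objective surface is
    shallow because lambda50 lies outside the measured range."""
    m_factors = (1.0, 0.5, 2.0, 0.25, 4.0, 8.0, 0.125)
    l50_shifts = (0.0, 5.0, -5.0, 10.0, 15.0, -10.0, 20.0)
    variants = []
    for k in range(min(n_max, len(m_factors))):
        variants.append(
            replace(init, m=init.m * m_factors[k], lambda50=init.lambda50 + l50_shifts[k])
        )
    return variants


def _identifiable(profile_csm: np.ndarray) -> bool:
    # a flat profile carries no information about m / lambda50 / csm_r
    return float(np.ptp(profile_csm)) > 1e-9


def fit_single(
    profile: CSMProfile,
    constants: REESConstants = REESConstants(),
    options: FitOptions = FitOptions(),
) -> tuple[REESParams, FitDiagnostics]:
    """Bounded least squares for one profile, all four parameters free.

    Deterministic given options (multi-start uses fixed perturbations).
    A flat, non-identifiable profile is returned flagged rather than
    raising: the parameters are the best found but cannot be trusted.
    """
    if len(profile) < 4:
        raise ValueError(
            f"profile has {len(profile)} points; need >= 4 for a 4-parameter fit"
        )
    init = initialize_params(profile, constants)
    lx = profile.excitation_wavelengths
    y = profile.csm
    RT = constants.RT
    lo = np.append(_LOCAL_LO, options.csm_r_bounds[0])
    hi = np.append(_LOCAL_HI, options.csm_r_bounds[1])

    def residuals(theta):
        pred, _, _ = _sigmoid_terms(theta[:3], theta[3], lx, RT)
        return pred - y

    def jac(theta):
        return _local_jacobian(theta[:3], theta[3], lx, RT)

    best = None
    for start in _start_variants(init, options, options.n_starts):
        theta0 = np.clip(
            [start.csm_fc, start.m, start.lambda50, start.csm_r], lo, hi
        )
        res = least_squares(
            residuals,
            theta0,
            jac=jac,
            bounds=(lo, hi),
            method="trf",
            ftol=options.ftol,
            xtol=options.xtol,
            gtol=options.gtol,
            max_nfev=options.max_nfev,
        )
        if best is None or res.cost < best.cost:
            best = res
    theta = best.x
    params = REESParams(csm_fc=theta[0], m=theta[1], lambda50=theta[2], csm_r=theta[3])
    diagnostics = FitDiagnostics(
        converged=bool(best.success),
        identifiable=_identifiable(y),
        n_evaluations=int(best.nfev),
        objective=float(2.0 * best.cost),
        message=best.message,
    )
    return params, diagnostics


def _group_profiles_by_sample(profiles):
    order: dict[str, list] = {}
    for p in profiles:
        order.setdefault(p.sample_id, []).append(p)
    return order


def fit_group_global(
    profiles,
    constants: REESConstants = REESConstants(),
    options: FitOptions = FitOptions(),
) -> GroupFitResult:
    """Joint fit of a group with one shared relaxed-state CSM.

    All profiles must carry the same group label.  The parameter vector
    is [csm_r_shared, (csm_fc, m, lambda50) per fitting unit]; fitting
    units are individual replicates by default, or per-sample replicate
    averages when ``options.share_csm_r == "sample_means"``.  The shared
    csm_r standard error comes from the fit covariance
    (s^2 * inv(J'J)); per-sample parameter spread is reported separately
    as the mean +/- sd over replicates.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles supplied")
    labels = {p.group_label for p in profiles}
    if len(labels) > 1:
        raise ValueError(f"mixed group labels in one global fit: {sorted(labels)}")
    group_label = profiles[0].group_label

    if options.share_csm_r == "sample_means":
        units = [_average_profile(ps) for ps in _group_profiles_by_sample(profiles).values()]
    else:
        units = profiles
    for p in units:
        if len(p) < 4:
            raise ValueError(
                f"profile {p.sample_id!r} rep {p.replicate_index} has {len(p)} "
                "points; need >= 4"
            )

    RT = constants.RT
    n_units = len(units)
    inits = [initialize_params(p, constants) for p in units]
    lx_list = [p.excitation_wavelengths for p in units]
    y_all = np.concatenate([p.csm for p in units])
    sizes = [len(p) for p in units]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    lo = np.concatenate([[options.csm_r_bounds[0]], np.tile(_LOCAL_LO, n_units)])
    hi = np.concatenate([[options.csm_r_bounds[1]], np.tile(_LOCAL_HI, n_units)])

    def unpack(theta):
        return theta[0], theta[1:].reshape(n_units, 3)

    def residuals(theta):
        csm_r, locals_ = unpack(theta)
        out = np.empty_like(y_all)
        for i in range(n_units):
            pred, _, _ = _sigmoid_terms(locals_[i], csm_r, lx_list[i], RT)
            out[offsets[i]:offsets[i + 1]] = pred
        return out - y_all

    def jac(theta):
        csm_r, locals_ = unpack(theta)
        J = np.zeros((y_all.size, theta.size))
        for i in range(n_units):
            block = _local_jacobian(locals_[i], csm_r, lx_list[i], RT)
            rows = slice(offsets[i], offsets[i + 1])
            J[rows, 0] = block[:, 3]
            J[rows, 1 + 3 * i: 4 + 3 * i] = block[:, :3]
        return J

    m_factors = (1.0, 0.5, 2.0, 0.25, 4.0)
    best = None
    for k in range(min(options.n_starts, len(m_factors))):
        theta0 = np.empty(1 + 3 * n_units)
        theta0[0] = 0.5 * sum(options.csm_r_bounds)
        for i, init in enumerate(inits):
            theta0[1 + 3 * i: 4 + 3 * i] = (
                init.csm_fc,
                init.m * m_factors[k],
                init.lambda50 + 5.0 * k,
            )
        theta0 = np.clip(theta0, lo, hi)
        res = least_squares(
            residuals,
            theta0,
            jac=jac,
            bounds=(lo, hi),
            method="trf",
            ftol=options.ftol,
            xtol=options.xtol,
            gtol=options.gtol,
            max_nfev=options.max_nfev,
        )
        if best is None or res.cost < best.cost:
            best = res

    csm_r, locals_ = unpack(best.x)
    per_replicate = tuple(
        ReplicateFit(
            sample_id=units[i].sample_id,
            replicate_index=units[i].replicate_index,
            params=REESParams(
                csm_fc=locals_[i, 0], m=locals_[i, 1], lambda50=locals_[i, 2], csm_r=csm_r
            ),
            residual_norm=float(
                np.linalg.norm(
                    best.fun[offsets[i]: offsets[i + 1]]
                )
            ),
        )
        for i in range(n_units)
    )
    shared_se = _shared_csm_r_se(best, n_obs=y_all.size)
    diagnostics = FitDiagnostics(
        converged=bool(best.success),
        identifiable=all(_identifiable(p.csm) for p in units),
        n_evaluations=int(best.nfev),
        objective=float(2.0 * best.cost),
        message=best.message,
    )
    summary = _per_sample_summary(per_replicate)
    return GroupFitResult(
        group_label=group_label,
        shared_csm_r=float(csm_r),
        shared_csm_r_se=shared_se,
        per_replicate=per_replicate,
        per_sample_summary=summary,
        diagnostics=diagnostics,
    )


def _average_profile(profiles):
    """Replicate-averaged CSM profile for 'sample_means' sharing."""
    base = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.excitation_wavelengths, base.excitation_wavelengths):
            raise ValueError(
                f"replicates of {base.sample_id!r} measured on different "
                "excitation grids"
            )
    mean_csm = np.mean([p.csm for p in profiles], axis=0)
    return CSMProfile(
        sample_id=base.sample_id,
        group_label=base.group_label,
        replicate_index=1,
        excitation_wavelengths=base.excitation_wavelengths,
        csm=mean_csm,
        emission_window=base.emission_window,
    )


def _shared_csm_r_se(res, n_obs: int) -> float:
    n_par = res.x.size
    dof = n_obs - n_par
    if dof <= 0:
        return float("nan")
    s2 = 2.0 * res.cost / dof
    J = res.jac
    try:
        cov = s2 * np.linalg.pinv(J.T @ J)
        return float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        return float("nan")


def _per_sample_summary(per_replicate) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "replicate": r.replicate_index,
            "csm_fc": r.params.csm_fc,
            "m": r.params.m,
            "lambda50": r.params.lambda50,
        }
        for r in per_replicate
    ]
    df = pd.DataFrame(rows)
    agg = df.groupby("sample_id", sort=False).agg(
        csm_fc_avg=("csm_fc", "mean"),
        csm_fc_sd=("csm_fc", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        m_avg=("m", "mean"),
        m_sd=("m", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        lambda50_avg=("lambda50", "mean"),
        lambda50_sd=("lambda50", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        n_replicates=("replicate", "count"),
    )
    return agg


def summarize_table(results, options: FitOptions = FitOptions()) -> pd.DataFrame:
    """Parameter table: one row per sample plus a group-mean row per group.

    Group means are means of per-sample means (each sample's triplicate
    average counts once), with sd over the per-sample means (ddof=1).
    ``options.m_display_scale`` rescales the slope columns for display.
    """
    results = list(results)
    if not results:
        raise ValueError("no fit results supplied")
    scale = options.m_display_scale
    frames = []
    for res in results:
        df = res.per_sample_summary.reset_index()
        df.insert(1, "group", res.group_label)
        df["m_avg"] = df["m_avg"] * scale
        df["m_sd"] = df["m_sd"] * scale
        df["csm_r"] = res.shared_csm_r
        df["csm_r_se"] = res.shared_csm_r_se
        df["row_type"] = "sample"
        frames.append(df)
        group_row = {
            "sample_id": res.group_label,
            "group": res.group_label,
            "csm_fc_avg": df["csm_fc_avg"].mean(),
            "csm_fc_sd": df["csm_fc_avg"].std(ddof=1) if len(df) > 1 else 0.0,
            "m_avg": df["m_avg"].mean(),
            "m_sd": df["m_avg"].std(ddof=1) if len(df) > 1 else 0.0,
            "lambda50_avg": df["lambda50_avg"].mean(),
            "lambda50_sd": df["lambda50_avg"].std(ddof=1) if len(df) > 1 else 0.0,
            "n_replicates": int(df["n_replicates"].sum()),
            "csm_r": res.shared_csm_r,
            "csm_r_se": res.shared_csm_r_se,
            "row_type": "group_mean",
        }
        frames.append(pd.DataFrame([group_row]))
    return pd.concat(frames, ignore_index=True)
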