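"""Synthetic excitation-emission data with known REES parameters.

The generator inverts the analysis: given target sigmoid parameters it
emits, for every excitation wavelength, a Gaussian emission band whose
*discrete, window-truncated* centre of spectral mass equals the target
CSM exactly (the band centre is solved for numerically, so truncation
at the window edges never biases the target).  Cohorts mirror the
two-group antibody study design: 18 samples with 22 Trp vs 3 samples
with 24 Trp, triplicate measurements, a relaxed-state CSM shared within
each group, and per-sample (CSM_FC, m, lambda50) drawn from group
distributions.

Noise can be injected at intensity level (Gaussian counts noise on the
band, the realistic mode) and/or directly as Gaussian jitter of the
per-point CSM (the fast mode for fitter benchmarking).  All randomness
flows through one seeded :class:`numpy.random.Generator`.

``make_toy_structure`` builds small deterministic coordinate models
with analytically known burial properties for exercising the SASA
stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csm import DEFAULT_WINDOW, compute_csm
from .model import REESConstants, REESParams, model_csm
from .sasa import StructureModel, VDW_RADII
from .spectra_io import EmissionSpectrum, SampleScan

__all__ = [
    "GroupSpec",
    "NoiseSpec",
    "CohortSpec",
    "study_cohort_spec",
    "solve_band_center",
    "gaussian_band",
    "simulate_scan",
    "simulate_cohort",
    "make_toy_structure",
    "TOY_STRUCTURES",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise configuration.

    intensity_sd: additive Gaussian sd on intensities, as a fraction of
    the band peak (clipped at zero afterwards).  csm_jitter_sd: Gaussian
    sd (nm) added to each target CSM before band construction.
    """

    intensity_sd: float = 0.0
    csm_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity_sd < 0 or self.csm_jitter_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """Parameter distributions for one cohort group.

    Per-sample csm_fc, m and lambda50 are drawn from normal
    distributions (mean, sd); csm_r is a single shared value for the
    whole group.
    """

    label: str
    n_samples: int
    csm_fc: tuple[float, float]
    m: tuple[float, float]
    lambda50: tuple[float, float]
    csm_r: float
    n_trp: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"group {self.label!r}: n_samples must be >= 1")
        for name in ("csm_fc", "m", "lambda50"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"group {self.label!r}: {name} sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full design of a simulated cohort."""

    groups: tuple[GroupSpec, ...]
    replicates: int = 3
    excitation: tuple[float, float, float] = (292.0, 310.0, 1.0)  # start, stop, step
    emission: tuple[float, float, float] = (325.0, 500.0, 1.0)
    band_sd: float = 25.0  # Gaussian band sd in nm (~59 nm FWHM)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.band_sd < 0:
            raise ValueError("band_sd must be >= 0")

    def excitation_grid(self) -> np.ndarray:
        lo, hi, step = self.excitation
        return np.arange(lo, hi + step / 2, step)

    def emission_grid(self) -> np.ndarray:
        lo, hi, step = self.emission
        return np.arange(lo, hi + step / 2, step)


def study_cohort_spec(
    seed: int = 0, noise: NoiseSpec | None = None, replicates: int = 3
) -> CohortSpec:
    """Cohort matching the antibody study design and parameter scales.

    18 IgG3-Arg292-like samples (22 Trp; csm_fc ~ N(352.9, 0.3) nm,
    shared csm_r 418.9 nm) and 3 IgG3-Trp292-like samples (24 Trp;
    csm_fc ~ N(353.9, 0.3) nm, shared csm_r 423.3 nm), triplicates.
    Slope terms are drawn around 470 / 520 J mol^-1 nm^-1 (higher for
    the more rigid 24-Trp group) so the sigmoid's rising tail over the
    292-310 nm window has the few-nm magnitude seen in measured
    profiles; inflection points sit just beyond the measurable range.
    """
    return CohortSpec(
        groups=(
            GroupSpec(
                label="IgG3-Arg292",
                n_samples=18,
                csm_fc=(352.9, 0.3),
                m=(470.0, 30.0),
                lambda50=(320.0, 2.0),
                csm_r=418.9,
                n_trp=22,
            ),
            GroupSpec(
                label="IgG3-Trp292",
                n_samples=3,
                csm_fc=(353.9, 0.3),
                m=(520.0, 30.0),
                lambda50=(320.0, 2.0),
                csm_r=423.3,
                n_trp=24,
            ),
        ),
        replicates=replicates,
        noise=noise if noise is not None else NoiseSpec(csm_jitter_sd=0.1),
        seed=seed,
    )


def _truncated_band_csm(center: float, band_sd: float, grid: np.ndarray) -> float:
    f = np.exp(-0.5 * ((grid - center) / band_sd) ** 2)
    total = f.sum()
    if total <= 0:
        return float("nan")
    return float(np.dot(f, grid) / total)


def solve_band_center(
    target_csm: float,
    band_sd: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
    step: float = 1.0,
    tol: float = 1e-6,
) -> float:
    """Band centre whose window-truncated discrete CSM hits the target.

    Truncation at the window edges pulls the CSM of an off-centre band
    towards the window interior, so the centre generally differs from
    the target; monotone bisection recovers it to ``tol`` nm.  A zero
    width band is a point mass: the centre is the target itself.
    """
    lo, hi = window
    if not lo <= target_csm <= hi:
        raise ValueError(f"target CSM {target_csm:g} outside window [{lo:g}, {hi:g}]")
    if band_sd <= 0:
        return float(target_csm)
    grid = np.arange(lo, hi + step / 2, step)
    # the truncated CSM is bounded away from the window edges; check reach
    span = 10.0 * band_sd + (hi - lo)
    a, b = lo - span, hi + span
    fa = _truncated_band_csm(a, band_sd, grid) - target_csm
    fb = _truncated_band_csm(b, band_sd, grid) - target_csm
    if fa > 0 or fb < 0:
        raise ValueError(
            f"target CSM {target_csm:g} nm unattainable with band sd "
            f"{band_sd:g} nm inside window [{lo:g}, {hi:g}] nm"
        )
    for _ in range(200):
        mid = 0.5 * (a + b)
        fm = _truncated_band_csm(mid, band_sd, grid) - target_csm
        if abs(fm) < tol:
            return float(mid)
        if fm < 0:
            a = mid
        else:
            b = mid
    raise RuntimeError("band-centre bisection failed to converge")


def gaussian_band(grid: np.ndarray, center: float, band_sd: float) -> np.ndarray:
    """Unit-peak Gaussian band sampled on the emission grid."""
    if band_sd <= 0:
        f = np.zeros_like(grid)
        f[np.argmin(np.abs(grid - center))] = 1.0
        return f
    return np.exp(-0.5 * ((grid - center) / band_sd) ** 2)


def simulate_scan(
    params: REESParams,
    spec: CohortSpec,
    rng: np.random.Generator | int,
    *,
    sample_id: str = "sim",
    group_label: str = "sim-group",
    replicate_index: int = 1,
    n_trp: int | None = None,
    constants: REESConstants = REESConstants(),
) -> SampleScan:
    """One full excitation-emission scan following the sigmoid model.

    Noise-free, ``compute_csm`` of every spectrum reproduces
    ``model_csm`` at that excitation to the band-centre solver
    tolerance.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    em_grid = spec.emission_grid()
    window = (float(em_grid[0]), float(em_grid[-1]))
    spectra = []
    for lx in spec.excitation_grid():
        target = model_csm(float(lx), params, constants)
        if spec.noise.csm_jitter_sd > 0:
            target += rng.normal(0.0, spec.noise.csm_jitter_sd)
        target = float(np.clip(target, window[0], window[1]))
        center = solve_band_center(target, spec.band_sd, window, step=spec.emission[2])
        f = gaussian_band(em_grid, center, spec.band_sd)
        if spec.noise.intensity_sd > 0:
            f = np.clip(f + rng.normal(0.0, spec.noise.intensity_sd, f.size), 0.0, None)
        spectra.append(EmissionSpectrum(float(lx), em_grid, f))
    return SampleScan(
        sample_id=sample_id,
        group_label=group_label,
        replicate_index=replicate_index,
        spectra=tuple(spectra),
        n_trp=n_trp,
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list[SampleScan], pd.DataFrame]:
    """Draw a full cohort; returns scans plus the ground-truth table.

    Replicates of a sample share that sample's generating parameters;
    replicate-to-replicate variation comes only from the noise model.
    The truth table has one row per sample: sample_id, group, csm_fc, m,
    lambda50, csm_r, n_trp.
    """
    rng = np.random.default_rng(spec.seed)
    scans: list[SampleScan] = []
    truth_rows = []
    for group in spec.groups:
        for s in range(group.n_samples):
            sample_id = f"{group.label}-s{s + 1:02d}"
            params = REESParams(
                csm_fc=rng.normal(*group.csm_fc),
                m=max(rng.normal(*group.m), 1e-3),
                lambda50=rng.normal(*group.lambda50),
                csm_r=group.csm_r,
            )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "group": group.label,
                    "csm_fc": params.csm_fc,
                    "m": params.m,
                    "lambda50": params.lambda50,
                    "csm_r": params.csm_r,
                    "n_trp": group.n_trp,
                }
            )
            for rep in range(1, spec.replicates + 1):
                scans.append(
                    simulate_scan(
                        params,
                        spec,
                        rng,
                        sample_id=sample_id,
                        group_label=group.label,
                        replicate_index=rep,
                        n_trp=group.n_trp,
                    )
                )
    return scans, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# toy coordinate models for the SASA stack

# idealised heavy-atom tryptophan residue (backbone + indole), Angstrom;
# geometry is approximate but deterministic and chemically plausible
_TRP_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("N", "N", (-1.458, 0.000, 0.000)),
    ("CA", "C", (0.000, 0.000, 0.000)),
    ("C", "C", (0.767, 1.280, 0.000)),
    ("O", "O", (0.190, 2.360, 0.110)),
    ("CB", "C", (0.610, -0.780, -1.170)),
    ("CG", "C", (2.060, -1.100, -1.010)),
    ("CD1", "C", (3.060, -0.300, -1.450)),
    ("NE1", "N", (4.260, -0.890, -1.150)),
    ("CE2", "C", (4.060, -2.090, -0.510)),
    ("CD2", "C", (2.660, -2.280, -0.400)),
    ("CE3", "C", (2.110, -3.420, 0.190)),
    ("CZ3", "C", (2.960, -4.400, 0.680)),
    ("CH2", "C", (4.340, -4.220, 0.580)),
    ("CZ2", "C", (4.930, -3.080, -0.010)),
]

TOY_STRUCTURES = ("isolated-trp", "two-isolated-trp", "buried-trp", "homodimer-two-rotamers")


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _trp_atoms(chain: str, resnum: int, offset, rotate: np.ndarray | None = None):
    rows = []
    for name, element, xyz in _TRP_TEMPLATE:
        pos = np.asarray(xyz, dtype=float)
        if rotate is not None and name not in ("N", "CA", "C", "O"):
            pos = rotate @ pos
        rows.append((chain, str(resnum), "TRP", name, element, pos + np.asarray(offset)))
    return rows


def _shell_atoms(chain: str, start_resnum: int, center, r_inner: float, r_outer: float,
                 spacing: float = 1.8):
    """Cubic-grid carbon shell between two radii around ``center``.

    Spacing well below twice the expanded-sphere radius leaves no gap a
    1.4 A probe could reach through, so anything the shell encloses has
    zero SASA.
    """
    center = np.asarray(center, dtype=float)
    ticks = np.arange(-r_outer, r_outer + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ticks, ticks, ticks, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    dist = np.linalg.norm(pts, axis=1)
    pts = center + pts[(dist >= r_inner) & (dist <= r_outer)]
    return [
        (chain, str(start_resnum + i), "UNK", "C", "C", pts[i])
        for i in range(len(pts))
    ]


def _build(rows) -> StructureModel:
    return StructureModel(
        chain_ids=np.array([r[0] for r in rows]),
        residue_numbers=np.array([r[1] for r in rows]),
        residue_names=np.array([r[2] for r in rows]),
        atom_names=np.array([r[3] for r in rows]),
        elements=np.array([r[4] for r in rows]),
        coords=np.array([r[5] for r in rows], dtype=float),
        radii=np.array([VDW_RADII[r[4]] for r in rows], dtype=float),
    )


def make_toy_structure(kind: str) -> StructureModel:
    """Deterministic toy coordinate models with known burial properties.

    - "isolated-trp": one free tryptophan, every atom solvent exposed;
    - "two-isolated-trp": two identical copies 100 A apart (additivity
      and symmetry checks);
    - "buried-trp": a tryptophan enclosed in a dense carbon shell, SASA
      exactly zero by construction;
    - "homodimer-two-rotamers": chains A and B carry one Trp each in
      different side-chain rotamers, chain B's rotamer packed against a
      carbon slab so the two copies have unequal exposure.
    """
    if kind == "isolated-trp":
        return _build(_trp_atoms("A", 1, (0.0, 0.0, 0.0)))
    if kind == "two-isolated-trp":
        rows = _trp_atoms("A", 1, (0.0, 0.0, 0.0)) + _trp_atoms("B", 1, (100.0, 0.0, 0.0))
        return _build(rows)
    if kind == "buried-trp":
        center = np.mean([xyz for _, _, xyz in _TRP_TEMPLATE], axis=0)
        rows = _trp_atoms("A", 1, (0.0, 0.0, 0.0))
        rows += _shell_atoms("A", 2, center, r_inner=4.8, r_outer=8.6, spacing=1.4)
        return _build(rows)
    if kind == "homodimer-two-rotamers":
        rot = _rotation(np.array([0.0, 0.0, 1.0]), np.deg2rad(110.0))
        rows = _trp_atoms("A", 1, (0.0, 0.0, 0.0))
        rows += _trp_atoms("B", 1, (30.0, 0.0, 0.0), rotate=rot)
        # carbon slab hugging chain B's side chain
        slab = []
        for ix in range(6):
            for iy in range(6):
                slab.append(
                    ("C", str(10 + ix * 6 + iy), "UNK", "C", "C",
                     np.array([27.0 + 1.6 * ix, -4.0 + 1.6 * iy, -3.5]))
                )
        return _build(rows + slab)
    raise ValueError(f"unknown toy structure {kind!r}; known: {TOY_STRUCTURES}")
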