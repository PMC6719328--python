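"""Synthetic glioma cohort with known ground truth.

Generates everything the clinical study measured, for a cohort of seven
low-grade and seven high-grade glioma subjects: voxelwise ground-truth
tissue parameters, multi-shell diffusion-weighted volumes under the
five-shell protocol with paired b0 images and Rician noise, a clinical
b=0/1000 pair for the conventional ADC, two observers' lesion masks,
per-subject histology tables with fixation shrinkage, and clinical
metadata.

Group presets encode the published group statistics as truncated normal
distributions: values are truncated to the printed ranges, and the
location parameter is calibrated so that the *median* of the truncated
distribution equals the printed central value (the published group values
are medians, and truncation at an asymmetric range would otherwise shift
them).  Voxelwise parameter fields are spatially smooth but keep these
marginals exactly, via a Gaussian copula: a smoothed white-noise field is
standardised and mapped through the truncated-normal quantile function.

Everything is driven by a single master seed and is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.optimize import brentq

from .analysis import HistologyFOV, ROIMask, SubjectRecord
from .models import voxel_signal  # noqa: F401  (re-exported convenience)
from .models import SphereModelConfig, ball_signal, sphere_signal
from .protocol import AcquisitionShell, Protocol, compute_b, five_shell_protocol

__all__ = [
    "TruncatedNormal",
    "GroupPreset",
    "PhantomSpec",
    "GroundTruth",
    "SyntheticSubject",
    "Cohort",
    "LGG_PRESET",
    "HGG_PRESET",
    "clinical_dwi_shell",
    "solve_d_ees",
    "make_phantom",
    "simulate_dwi",
    "simulate_clinical_pair",
    "make_observer_masks",
    "make_histology",
    "make_subject",
    "make_cohort",
]


# ---------------------------------------------------------------------------
# distributions


@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated normal parameterised by its median.

    ``median`` is the value the truncated distribution's 50% quantile must
    hit; the underlying location parameter is solved for accordingly (it
    differs from ``median`` whenever the truncation interval is asymmetric
    about it).  ``sd`` is the scale of the parent normal.
    """

    median: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.median <= self.high):
            raise ValueError("median must lie inside the truncation range")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @property
    def loc(self) -> float:
        if self.sd == 0:
            return self.median

        def med_of(loc: float) -> float:
            a = (self.low - loc) / self.sd
            b = (self.high - loc) / self.sd
            return stats.truncnorm.ppf(0.5, a, b, loc=loc, scale=self.sd) - self.median

        lo = self.median - 6 * self.sd
        hi = self.median + 6 * self.sd
        return brentq(med_of, lo, hi, xtol=1e-12)

    def ppf(self, u: np.ndarray | float) -> np.ndarray | float:
        if self.sd == 0:
            return np.full_like(np.asarray(u, dtype=float), self.median)
        loc = self.loc
        a = (self.low - loc) / self.sd
        b = (self.high - loc) / self.sd
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=self.sd)

    def rvs(self, rng: np.random.Generator, size: int | tuple = 1):
        return self.ppf(rng.uniform(size=size))


# ---------------------------------------------------------------------------
# presets


@dataclass(frozen=True)
class GroupPreset:
    """Published group-level distributions for one tumour grade."""

    group: str
    f_ic: TruncatedNormal
    f_ec: TruncatedNormal
    radius_um: TruncatedNormal
    adc_target: float  # two-point ADC, mm^2/s
    cellularity: TruncatedNormal  # cells per histology field
    shrinkage: float  # fixed-tissue size / fresh-tissue size

    def __post_init__(self) -> None:
        if self.group not in ("LGG", "HGG"):
            raise ValueError("group must be 'LGG' or 'HGG'")
        if not (0 < self.shrinkage <= 1.5):
            raise ValueError("implausible shrinkage factor")


#: Red-blood-cell diameters: 5.5 um on fixed sections vs 7.6 um fresh.
RBC_SHRINKAGE = 5.5 / 7.6

LGG_PRESET = GroupPreset(
    group="LGG",
    f_ic=TruncatedNormal(0.08, 0.02, 0.07, 0.14),
    f_ec=TruncatedNormal(0.92, 0.04, 0.85, 0.95),
    radius_um=TruncatedNormal(6.7, 1.2, 4.8, 7.8),
    adc_target=1.22e-3,
    cellularity=TruncatedNormal(51.0, 66.4, 35.0, 210.0),
    shrinkage=RBC_SHRINKAGE,
)

HGG_PRESET = GroupPreset(
    group="HGG",
    f_ic=TruncatedNormal(0.13, 0.07, 0.08, 0.27),
    f_ec=TruncatedNormal(0.88, 0.07, 0.75, 0.92),
    radius_um=TruncatedNormal(6.8, 2.3, 4.3, 11.0),
    adc_target=0.98e-3,
    cellularity=TruncatedNormal(104.0, 43.0, 67.0, 170.0),
    shrinkage=RBC_SHRINKAGE,
)

# demographics (used only for metadata tables)
_DEMOGRAPHICS = {
    "LGG": dict(
        age=TruncatedNormal(33.2, 9.2, 24.0, 45.0),
        mib1=TruncatedNormal(4.2, 3.0, 1.0, 8.8),
        size=TruncatedNormal(44.4, 19.1, 23.1, 68.7),
        p_male=2 / 7,
        idh="present",
    ),
    "HGG": dict(
        age=TruncatedNormal(55.3, 11.9, 44.0, 78.0),
        mib1=TruncatedNormal(19.2, 6.7, 12.0, 31.0),
        size=TruncatedNormal(27.1, 17.2, 6.4, 56.4),
        p_male=4 / 7,
        idh="absent",
    ),
}


# ---------------------------------------------------------------------------
# protocol helpers


def clinical_dwi_shell(b: float = 1000.0, Delta: float = 35.0, delta: float = 25.0,
                       TE: float = 85.0) -> AcquisitionShell:
    """A clinical-DWI-style shell with |G| solved to hit the nominal b.

    The conventional ADC acquisition (b = 0 and 1000 s/mm^2) does not
    publish its pulse timings, so plausible clinical values are used and
    the gradient amplitude is chosen to make the Stejskal--Tanner b exact.
    """
    from .protocol import GAMMA_PROTON

    b_si = b * 1e6
    g = math.sqrt(b_si / (GAMMA_PROTON**2 * (delta * 1e-3) ** 2 * ((Delta - delta / 3) * 1e-3)))
    return AcquisitionShell(b_nominal=b, Delta=Delta, delta=delta, G=g * 1e3, TE=TE,
                            n_averages=1, has_paired_b0=True)


def solve_d_ees(preset: GroupPreset, shell: AcquisitionShell | None = None,
                d_ic: float = 2.0e-9) -> float:
    """Extracellular diffusivity that reproduces the group's two-point ADC.

    The published ADC constrains the only free diffusivity of the tissue
    model: with the group-median f_ic, f_ec and radius fixed, solve

        ADC = ln[(f_ic + f_ec) / (f_ic S_sphere(b) + f_ec e^{-b d})] / b

    for d at b = 1000 s/mm^2.
    """
    if shell is None:
        shell = clinical_dwi_shell()
    b = compute_b(shell)  # s/mm^2
    f_ic = preset.f_ic.median
    f_ec = preset.f_ec.median
    s_sph = sphere_signal(shell, preset.radius_um.median, d_ic)

    def eqn(d: float) -> float:
        s = f_ic * s_sph + f_ec * math.exp(-b * 1e6 * d)
        return math.log((f_ic + f_ec) / s) / b - preset.adc_target

    return brentq(eqn, 1e-10, 3.5e-9, xtol=1e-15)


# ---------------------------------------------------------------------------
# phantom


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise description of one synthetic subject."""

    shape: tuple[int, int, int] = (32, 32, 16)
    voxel_mm: float = 2.0
    snr: float = 50.0
    smooth_sigma_vox: float = 1.5  # spatial correlation scale of the fields
    t2_s: float = 0.1  # mono-exponential T2 for the per-shell S0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if any(n < 8 for n in self.shape):
            raise ValueError("phantom too small for a lesion")


#: region labels
BACKGROUND, BRAIN, TUMOUR, OEDEMA = 0, 1, 2, 3

# normal-appearing brain: ball-dominant, modest restriction
_BRAIN_PARAMS = dict(f_ic=0.35, f_ec=0.62, radius_um=5.0, d_ees=0.9e-9)


@dataclass
class GroundTruth:
    """Voxelwise ground-truth tissue parameters plus the region label map."""

    labels: np.ndarray  # int, phantom regions
    f_ic: np.ndarray
    f_ec: np.ndarray
    radius_um: np.ndarray
    d_ees: np.ndarray
    spec: PhantomSpec

    @property
    def lesion_mask(self) -> np.ndarray:
        return (self.labels == TUMOUR) | (self.labels == OEDEMA)


def _copula_field(shape: tuple[int, int, int], dist: TruncatedNormal,
                  sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field with an exact truncated-normal marginal."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    z = (z - z.mean()) / max(z.std(), 1e-12)
    u = stats.norm.cdf(z)
    # keep quantiles strictly inside (0,1)
    u = np.clip(u, 1e-9, 1 - 1e-9)
    return np.asarray(dist.ppf(u), dtype=float)


def make_phantom(spec: PhantomSpec, preset: GroupPreset,
                 rng: np.random.Generator) -> GroundTruth:
    """Build one subject: brain slab, ellipsoidal tumour, oedema rim.

    Tissue parameters inside the tumour (and its oedema rim, which the
    whole-lesion ROI includes) are drawn voxelwise from the group preset
    with spatial smoothing; normal brain gets fixed nominal values.
    """
    nx, ny, nz = spec.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2

    brain = (((ii - cx) / (0.45 * nx)) ** 2 + ((jj - cy) / (0.45 * ny)) ** 2
             + ((kk - cz) / (0.45 * nz)) ** 2) <= 1.0

    # tumour centre jittered off-centre; semi-axes ~1/5 of the grid
    centre = np.array([cx, cy, cz]) + rng.uniform(-2, 2, size=3)
    semi = np.array([0.22 * nx, 0.22 * ny, 0.25 * nz]) * rng.uniform(0.85, 1.15, size=3)
    r2 = (((ii - centre[0]) / semi[0]) ** 2 + ((jj - centre[1]) / semi[1]) ** 2
          + ((kk - centre[2]) / semi[2]) ** 2)
    tumour = (r2 <= 1.0) & brain
    oedema = (r2 <= 1.45**2) & brain & ~tumour
    if not tumour.any():
        raise ValueError("phantom spec produced an empty tumour region")

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[brain] = BRAIN
    labels[oedema] = OEDEMA
    labels[tumour] = TUMOUR

    f_ic = np.zeros(spec.shape)
    f_ec = np.zeros(spec.shape)
    radius = np.full(spec.shape, 1.0)
    d_ees = np.full(spec.shape, _BRAIN_PARAMS["d_ees"])

    f_ic[brain] = _BRAIN_PARAMS["f_ic"]
    f_ec[brain] = _BRAIN_PARAMS["f_ec"]
    radius[brain] = _BRAIN_PARAMS["radius_um"]

    lesion = tumour | oedema
    f_ic[lesion] = _copula_field(spec.shape, preset.f_ic, spec.smooth_sigma_vox, rng)[lesion]
    f_ec[lesion] = _copula_field(spec.shape, preset.f_ec, spec.smooth_sigma_vox, rng)[lesion]
    radius[lesion] = _copula_field(spec.shape, preset.radius_um, spec.smooth_sigma_vox, rng)[lesion]
    d_ees[lesion] = solve_d_ees(preset)

    return GroundTruth(labels=labels, f_ic=f_ic, f_ec=f_ec, radius_um=radius,
                       d_ees=d_ees, spec=spec)


# ---------------------------------------------------------------------------
# signal simulation


def _forward_volumes(gt: GroundTruth, shell: AcquisitionShell,
                     sphere_cfg: SphereModelConfig) -> np.ndarray:
    """Noiseless normalised signal for one shell, vectorised by radius lookup."""
    tissue = gt.labels > 0
    out = np.zeros(gt.labels.shape)
    # sphere term: interpolate the GPD signal on a fine radius grid
    r_grid = np.linspace(0.5, 16.0, 312)
    s_grid = sphere_signal(shell, r_grid, cfg=sphere_cfg)
    s_sphere = np.interp(gt.radius_um[tissue], r_grid, s_grid)
    b_si = compute_b(shell) * 1e6
    s_ball = np.exp(-b_si * gt.d_ees[tissue])
    out[tissue] = gt.f_ic[tissue] * s_sphere + gt.f_ec[tissue] * s_ball
    return out


def _rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    n1 = rng.normal(0.0, sigma, noiseless.shape)
    n2 = rng.normal(0.0, sigma, noiseless.shape)
    return np.sqrt((noiseless + n1) ** 2 + n2**2)


def simulate_dwi(gt: GroundTruth, protocol: Protocol, snr: float,
                 rng: np.random.Generator,
                 sphere_cfg: SphereModelConfig | None = None) -> np.ndarray:
    """Simulate the 4D acquisition: paired b0 per shell, Rician noise.

    Each shell's volumes are scaled by a shell-specific S0 = exp(-TE/T2) —
    the varying T2 weighting that makes the per-shell b0 normalisation
    necessary — and corrupted with Rician noise of scale sigma =
    S0_shell / SNR (the magnitude of a complex Gaussian perturbation).
    """
    if snr <= 0:
        raise ValueError("SNR must be positive")
    if sphere_cfg is None:
        sphere_cfg = SphereModelConfig()
    layout = protocol.measurement_layout()
    vols = np.empty(gt.labels.shape + (len(layout),))
    tissue = (gt.labels > 0).astype(float)
    for row, (ishell, is_b0) in enumerate(layout):
        shell = protocol.shells[ishell]
        s0_shell = math.exp(-shell.TE * 1e-3 / gt.spec.t2_s)
        if is_b0:
            noiseless = s0_shell * tissue * (gt.f_ic + gt.f_ec)
        else:
            noiseless = s0_shell * _forward_volumes(gt, shell, sphere_cfg)
        vols[..., row] = _rician(noiseless, s0_shell / snr, rng)
    return vols


def simulate_clinical_pair(gt: GroundTruth, snr: float, rng: np.random.Generator,
                           shell: AcquisitionShell | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the conventional b=0 / b=1000 s/mm^2 pair for the ADC map."""
    if shell is None:
        shell = clinical_dwi_shell()
    s0_amp = math.exp(-shell.TE * 1e-3 / gt.spec.t2_s)
    tissue = (gt.labels > 0).astype(float)
    s0 = s0_amp * tissue * (gt.f_ic + gt.f_ec)
    s_b = s0_amp * _forward_volumes(gt, shell, SphereModelConfig())
    sigma = s0_amp / snr
    return _rician(s0, sigma, rng), _rician(s_b, sigma, rng)


# ---------------------------------------------------------------------------
# observer masks


#: boundary perturbation (in mm) calibrated so the cohort-mean Dice between
#: the two observers is ~0.89, matching the reported inter-observer overlap
#: (calibration curve on the default lesion geometry:
#: 2.4 mm -> 0.92, 2.8 mm -> 0.89, 3.2 mm -> 0.87, 3.6 mm -> 0.84)
DEFAULT_OBSERVER_PERTURBATION_MM = 2.8


def make_observer_masks(gt: GroundTruth, perturbation_mm: float = DEFAULT_OBSERVER_PERTURBATION_MM,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[ROIMask, ROIMask]:
    """Two observers' whole-lesion masks.

    Observer 1 traces the true lesion (tumour plus oedema).  Observer 2's
    mask is generated by adding a smooth random field to the signed
    distance from the true boundary and re-thresholding, which dilates and
    erodes the outline locally — emulating inter-observer boundary
    disagreement whose magnitude grows with ``perturbation_mm``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    true_mask = gt.lesion_mask
    if not true_mask.any():
        raise ValueError("empty lesion; no masks to draw")
    if perturbation_mm < 0:
        raise ValueError("perturbation must be non-negative")
    vox = gt.spec.voxel_mm
    # signed distance, mm: negative inside the lesion
    inside = ndimage.distance_transform_edt(true_mask, sampling=vox)
    outside = ndimage.distance_transform_edt(~true_mask, sampling=vox)
    sdf = outside - inside
    noise = ndimage.gaussian_filter(rng.standard_normal(true_mask.shape), 2.0)
    noise /= max(noise.std(), 1e-12)
    obs2 = (sdf + perturbation_mm * noise) < 0
    if not obs2.any():
        raise ValueError("perturbation erased the second observer's mask")
    return (
        ROIMask(true_mask, label="whole_lesion", observer="obs1"),
        ROIMask(obs2, label="whole_lesion", observer="obs2"),
    )


# ---------------------------------------------------------------------------
# histology


def make_histology(preset: GroupPreset, subject_radius_um: float, n_fovs: int,
                   rng: np.random.Generator, n_cells_per_fov: int = 20,
                   ) -> tuple[list[HistologyFOV], np.ndarray]:
    """Per-field cell counts and axis measurements for one subject.

    Fresh-tissue cell radii scatter around the subject's ground-truth MRI
    radius; the recorded (fixed-section) axes are shrunk by the group's
    fixation factor.  Cell eccentricity is drawn uniformly so that the
    short/long axes average back to the generating radius exactly:
    short = 2r(1-e), long = 2r(1+e) gives (short+long)/4 = r.

    Returns the FOV list and the fresh-tissue radii (the pre-shrinkage
    truth, for shrinkage-correction tests).
    """
    if n_fovs < 1:
        raise ValueError("need at least one field of view")
    if subject_radius_um <= 0:
        raise ValueError("subject radius must be positive")
    fovs = []
    fresh_all = []
    for _ in range(n_fovs):
        count = int(round(float(preset.cellularity.rvs(rng, 1)[0])))
        fresh = subject_radius_um * np.clip(rng.normal(1.0, 0.15, n_cells_per_fov), 0.5, 1.5)
        fixed = fresh * preset.shrinkage
        ecc = rng.uniform(0.0, 0.25, n_cells_per_fov)
        axes = [(2 * r * (1 - e), 2 * r * (1 + e)) for r, e in zip(fixed, ecc)]
        fovs.append(HistologyFOV(cell_count=count, axes_um=axes))
        fresh_all.append(fresh)
    return fovs, np.concatenate(fresh_all)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SyntheticSubject:
    """One simulated subject: truth, acquisitions, masks and histology."""

    record: SubjectRecord
    ground_truth: GroundTruth
    dwi: np.ndarray  # 4D, five-shell protocol measurement order
    clinical_s0: np.ndarray
    clinical_s1000: np.ndarray
    mask_obs1: ROIMask
    mask_obs2: ROIMask
    histology: list[HistologyFOV]
    fresh_radii_um: np.ndarray


@dataclass
class Cohort:
    subjects: list[SyntheticSubject]
    protocol: Protocol
    seed: int

    def by_grade(self, grade: str) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.record.grade == grade]


def _make_record(grade: str, idx: int, rng: np.random.Generator) -> SubjectRecord:
    d = _DEMOGRAPHICS[grade]
    return SubjectRecord(
        subject_id=f"{grade}{idx + 1:02d}",
        grade=grade,
        idh1_r132h=d["idh"],
        mib1=float(d["mib1"].rvs(rng, 1)[0]),
        lesion_size_mm=float(d["size"].rvs(rng, 1)[0]),
        age_years=float(d["age"].rvs(rng, 1)[0]),
        sex="M" if rng.uniform() < d["p_male"] else "F",
    )


def make_subject(grade: str, idx: int, spec: PhantomSpec, protocol: Protocol,
                 seed: int, n_fovs: int = 5) -> SyntheticSubject:
    """Fully simulate one subject from a per-subject seed."""
    preset = LGG_PRESET if grade == "LGG" else HGG_PRESET
    rng = np.random.default_rng(seed)
    record = _make_record(grade, idx, rng)
    gt = make_phantom(spec, preset, rng)
    dwi = simulate_dwi(gt, protocol, spec.snr, rng)
    s0, s1000 = simulate_clinical_pair(gt, spec.snr, rng)
    m1, m2 = make_observer_masks(gt, rng=rng)
    tumour_r = float(np.median(gt.radius_um[gt.labels == TUMOUR]))
    fovs, fresh = make_histology(preset, tumour_r, n_fovs, rng)
    return SyntheticSubject(
        record=record, ground_truth=gt, dwi=dwi,
        clinical_s0=s0, clinical_s1000=s1000,
        mask_obs1=m1, mask_obs2=m2, histology=fovs, fresh_radii_um=fresh,
    )


def make_cohort(n_lgg: int = 7, n_hgg: int = 7, snr: float = 50.0, seed: int = 17,
                shape: tuple[int, int, int] = (32, 32, 16),
                protocol: Protocol | None = None, n_fovs: int = 5) -> Cohort:
    """Simulate the full two-grade cohort from one master seed.

    Per-subject seeds are spawned deterministically from the master seed,
    so any subject can be regenerated independently and the whole cohort
    is byte-reproducible.
    """
    if protocol is None:
        protocol = five_shell_protocol()
    spec = PhantomSpec(snr=snr, shape=shape)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_lgg + n_hgg) % (2**31)
    subjects = []
    for i in range(n_lgg):
        subjects.append(make_subject("LGG", i, spec, protocol, int(child_seeds[i]), n_fovs))
    for i in range(n_hgg):
        subjects.append(make_subject("HGG", i, spec, protocol, int(child_seeds[n_lgg + i]), n_fovs))
    return Cohort(subjects=subjects, protocol=protocol, seed=seed)
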