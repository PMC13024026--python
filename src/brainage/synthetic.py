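"""Age-structured synthetic 3-D cohorts with known ground truth.

The generator emulates the *statistical* structure a lifespan brain-age
model must learn from gray-matter density maps, not MRI physics:

* a smooth anatomical template shared by all subjects;
* ``n_blobs`` regional structures whose amplitudes follow a piecewise-linear
  age trajectory — steep positive slope during development (before
  ``childhood_knot``), gentle negative slope during adulthood — with fixed
  per-region slope multipliers so the amplitude pattern identifies age
  uniquely despite the non-monotone total;
* multiplicative low-frequency site bias fields and site-dependent additive
  voxel noise;
* a global multiplicative sex factor and a small per-subject scale;
* optionally, noisy age *labels* (``age_label_noise_sd``) so that the
  Bayes-optimal mean-absolute error against recorded ages is
  ``sigma * sqrt(2/pi)``, giving an analytic yardstick for trained models.

Longitudinal pairs reuse all subject factors with the latent age advanced by
a known interval; test-retest pairs differ only in the noise draw.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .manifest import CohortManifest, ScanRecord
from .metrics import PredictionSet
from .volume import VolumeGrid, write_volume


@dataclass
class SimulationParams:
    grid_shape: tuple = (28, 34, 28)   # one-third scale; (84, 102, 84) = model scale
    n_subjects: int = 100
    age_range: tuple = (0.0, 96.0)
    n_blobs: int = 8
    childhood_knot: float = 18.0       # years; developmental / adult break
    child_slope: float = 0.03          # density change per year before the knot
    adult_slope: float = -0.004        # density change per year after the knot
    site_count: int = 3
    site_noise_sd: float = 0.02        # additive voxel noise scale
    site_bias_amplitude: float = 0.05  # multiplicative low-frequency bias
    sex_effect: float = 0.05           # global scale gap between sexes
    subject_scale_sd: float = 0.01     # per-subject template scale jitter
    age_label_noise_sd: float = 0.0    # sd of recorded-age noise, years
    seed: int = 0
    template_seed: int | None = None   # anatomy seed; None -> tied to `seed`

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.age_range
        if not (0.0 <= lo < hi <= 130.0):
            raise ValueError(f"age_range {self.age_range} must lie within [0, 130]")
        for name in ("child_slope", "adult_slope", "site_noise_sd",
                     "site_bias_amplitude", "sex_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        cap = int(np.prod([max(g // 4, 1) for g in self.grid_shape]))
        if self.n_blobs > cap:
            raise ValueError(
                f"grid {self.grid_shape} too small for {self.n_blobs} regional blobs "
                f"(capacity {cap})")


@dataclass
class GroundTruth:
    """Latent per-scan state and (for paired designs) true intervals."""

    scans: pd.DataFrame               # scan_id, subject_id, latent_age, site, sex
    pairs: pd.DataFrame | None = None  # subject_id, scan_id_1, scan_id_2, delta_y

    def latent_age(self, scan_id: str) -> float:
        row = self.scans.loc[self.scans["scan_id"] == scan_id]
        return float(row["latent_age"].iloc[0])

    def to_json(self, path) -> None:
        obj = {"scans": self.scans.to_dict(orient="records")}
        if self.pairs is not None:
            obj["pairs"] = self.pairs.to_dict(orient="records")
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        pairs = pd.DataFrame(obj["pairs"]) if "pairs" in obj else None
        return cls(pd.DataFrame(obj["scans"]), pairs)


class _CohortModel:
    """Deterministic cohort-level fields (template, blobs, site effects)."""

    def __init__(self, params: SimulationParams, rng: np.random.Generator):
        self.p = params
        D, H, W = params.grid_shape
        z, y, x = np.meshgrid(*(np.linspace(-1, 1, g) for g in (D, H, W)),
                              indexing="ij")
        r2 = z * z + y * y + x * x
        self.template = 0.6 * np.exp(-r2 / (2 * 0.45 ** 2))
        # fixed regional structures
        centers = rng.uniform(-0.6, 0.6, size=(params.n_blobs, 3))
        widths = rng.uniform(0.12, 0.22, size=params.n_blobs)
        self.blobs = np.stack([
            np.exp(-((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
                   / (2 * w ** 2))
            for c, w in zip(centers, widths)])
        # per-region slope multipliers make the amplitude pattern injective in age
        self.child_mult = rng.uniform(0.5, 1.5, size=params.n_blobs)
        self.adult_mult = rng.uniform(0.5, 1.5, size=params.n_blobs)
        self.base_amp = 0.1
        # per-site multiplicative bias field: low-order cosine modes
        fields = []
        for _ in range(params.site_count):
            coeff = rng.normal(size=(2, 2, 2))
            f = np.zeros_like(self.template)
            for i in range(2):
                for j in range(2):
                    for k in range(2):
                        f += coeff[i, j, k] * np.cos((i + 1) * math.pi * z / 2) \
                            * np.cos((j + 1) * math.pi * y / 2) \
                            * np.cos((k + 1) * math.pi * x / 2)
            f /= max(np.abs(f).max(), 1e-12)
            fields.append(f)
        self.site_fields = np.stack(fields)
        self.site_noise_mult = rng.uniform(0.75, 1.25, size=params.site_count)

    def blob_amplitudes(self, age: float) -> np.ndarray:
        p = self.p
        dev = min(age, p.childhood_knot)
        adult = max(0.0, age - p.childhood_knot)
        return (self.base_amp
                + p.child_slope * self.child_mult * dev
                + p.adult_slope * self.adult_mult * adult)

    def render(self, age, site, sex, subject_scale, rng) -> np.ndarray:
        p = self.p
        sex_factor = 1.0 + (0.5 if sex == "M" else -0.5) * p.sex_effect
        bias = 1.0 + p.site_bias_amplitude * self.site_fields[site]
        vol = self.template * bias * sex_factor * subject_scale
        amps = self.blob_amplitudes(age)
        vol = vol + np.tensordot(amps, self.blobs, axes=(0, 0))
        sd = p.site_noise_sd * self.site_noise_mult[site]
        if sd > 0:
            vol = vol + rng.normal(0.0, sd, size=vol.shape)
        return vol.astype(np.float32)


def _draw_subjects(model: _CohortModel, rng: np.random.Generator, n: int,
                   age_lo: float, age_hi: float):
    p = model.p
    ages = rng.uniform(age_lo, age_hi, size=n)
    sexes = np.where(rng.random(n) < 0.5, "M", "F")
    sites = rng.integers(0, p.site_count, size=n)
    scales = 1.0 + rng.normal(0.0, p.subject_scale_sd, size=n)
    return ages, sexes, sites, scales


def _label(rng: np.random.Generator, latent: float, sd: float) -> float:
    if sd <= 0:
        return float(latent)
    return float(np.clip(latent + rng.normal(0.0, sd), 0.0, 130.0))


def structural_model(params: SimulationParams) -> _CohortModel:
    """Cohort-level anatomy (template, blobs, site fields) for `params`.

    Seeded by ``template_seed`` (falling back to ``seed``), independently of
    the subject draws, so separate cohorts can share one anatomy.
    """
    tseed = params.seed if params.template_seed is None else params.template_seed
    return _CohortModel(params, np.random.default_rng([tseed, 0]))


def _model_and_subject_rng(params: SimulationParams):
    return structural_model(params), np.random.default_rng([params.seed, 1])


def generate_cohort(params: SimulationParams):
    """Cross-sectional cohort: one scan per subject, ages uniform on the range."""
    model, rng = _model_and_subject_rng(params)
    lo, hi = params.age_range
    ages, sexes, sites, scales = _draw_subjects(model, rng, params.n_subjects, lo, hi)
    vols = np.empty((params.n_subjects, *params.grid_shape), dtype=np.float32)
    records, rows = [], []
    for i in range(params.n_subjects):
        vols[i] = model.render(ages[i], sites[i], sexes[i], scales[i], rng)
        sid, scid = f"sub-{i:04d}", f"scan-{i:04d}"
        records.append(ScanRecord(scid, sid, _label(rng, ages[i], params.age_label_noise_sd),
                                  sexes[i], f"site{sites[i]}", "unsplit"))
        rows.append({"scan_id": scid, "subject_id": sid, "latent_age": float(ages[i]),
                     "site": int(sites[i]), "sex": str(sexes[i])})
    gt = GroundTruth(pd.DataFrame(rows))
    return CohortManifest(records, provenance="synthetic cross-sectional"), vols, gt


def generate_longitudinal_pairs(params: SimulationParams, interval_range=(1.0, 5.0)):
    """Baseline/follow-up pairs: same subject factors, latent age advanced."""
    if interval_range[0] < 0 or interval_range[1] < interval_range[0]:
        raise ValueError(f"interval_range must be non-negative and ordered, "
                         f"got {interval_range}")
    model, rng = _model_and_subject_rng(params)
    lo, hi = params.age_range
    base_hi = max(lo + 1e-6, hi - interval_range[1])
    ages, sexes, sites, scales = _draw_subjects(model, rng, params.n_subjects, lo, base_hi)
    deltas = rng.uniform(interval_range[0], interval_range[1], size=params.n_subjects)
    vols = np.empty((2 * params.n_subjects, *params.grid_shape), dtype=np.float32)
    records, rows, prows = [], [], []
    for i in range(params.n_subjects):
        sid = f"sub-{i:04d}"
        a1, a2 = float(ages[i]), float(ages[i] + deltas[i])
        ids = (f"scan-{i:04d}-bl", f"scan-{i:04d}-fu")
        for j, (a, role) in enumerate(zip((a1, a2),
                                          ("longitudinal_baseline", "longitudinal_followup"))):
            vols[2 * i + j] = model.render(a, sites[i], sexes[i], scales[i], rng)
            records.append(ScanRecord(ids[j], sid, _label(rng, a, params.age_label_noise_sd),
                                      sexes[i], f"site{sites[i]}", role))
            rows.append({"scan_id": ids[j], "subject_id": sid, "latent_age": a,
                         "site": int(sites[i]), "sex": str(sexes[i])})
        prows.append({"subject_id": sid, "scan_id_1": ids[0], "scan_id_2": ids[1],
                      "delta_y": float(deltas[i])})
    gt = GroundTruth(pd.DataFrame(rows), pd.DataFrame(prows))
    return CohortManifest(records, provenance="synthetic longitudinal"), vols, gt


def generate_retest_pairs(params: SimulationParams):
    """Test-retest pairs: identical latent state, independent noise draws."""
    model, rng = _model_and_subject_rng(params)
    lo, hi = params.age_range
    ages, sexes, sites, scales = _draw_subjects(model, rng, params.n_subjects, lo, hi)
    vols = np.empty((2 * params.n_subjects, *params.grid_shape), dtype=np.float32)
    records, rows, prows = [], [], []
    for i in range(params.n_subjects):
        sid = f"sub-{i:04d}"
        a = float(ages[i])
        label = _label(rng, a, params.age_label_noise_sd)
        ids = (f"scan-{i:04d}-r1", f"scan-{i:04d}-r2")
        for j, role in enumerate(("retest_1", "retest_2")):
            vols[2 * i + j] = model.render(a, sites[i], sexes[i], scales[i], rng)
            records.append(ScanRecord(ids[j], sid, label, sexes[i],
                                      f"site{sites[i]}", role))
            rows.append({"scan_id": ids[j], "subject_id": sid, "latent_age": a,
                         "site": int(sites[i]), "sex": str(sexes[i])})
        prows.append({"subject_id": sid, "scan_id_1": ids[0], "scan_id_2": ids[1],
                      "delta_y": 0.0})
    gt = GroundTruth(pd.DataFrame(rows), pd.DataFrame(prows))
    return CohortManifest(records, provenance="synthetic test-retest"), vols, gt


def oracle_predict(gt: GroundTruth) -> PredictionSet:
    """Predict the latent age itself — the perfect reference predictor."""
    s = gt.scans
    return PredictionSet(s["scan_id"].to_numpy(), s["latent_age"].to_numpy(),
                         s["latent_age"].to_numpy(), s["subject_id"].to_numpy())


def total_blob_mass(params: SimulationParams, age: float) -> float:
    """Sum of regional amplitudes at `age` — monotone within each life phase."""
    return float(structural_model(params).blob_amplitudes(age).sum())


def write_cohort(outdir, manifest: CohortManifest, vols: np.ndarray,
                 gt: GroundTruth, spacing=(2.0, 2.0, 2.0)):
    """Persist a generated cohort: NIfTI volumes, CSV manifest, JSON ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from dataclasses import replace
    records = []
    for rec, vol in zip(manifest.records, vols):
        p = outdir / "volumes" / f"{rec.scan_id}.nii.gz"
        write_volume(VolumeGrid(vol, spacing), p)
        records.append(replace(rec, path=str(p)))
    man = CohortManifest(records, manifest.provenance)
    man.to_csv(outdir / "manifest.csv")
    gt.to_json(outdir / "ground_truth.json")
    return man
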