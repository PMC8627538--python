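"""Synthetic multi-lesion PET cohorts with controlled intra-patient cohesion.

The generator emulates the structure of a recurrent prostate-cancer choline-PET
cohort: each patient carries a latent *phenotype archetype*; each of their
lesions is a draw around that archetype in radiomic feature space, shifted by
an anatomical-site effect and blurred by within-patient noise.  The ratio
``sigma_within / sigma_between`` is the single knob that controls how cohesive
a patient's lesions are relative to the rest of the cohort, which is exactly
what the downstream silhouette analysis measures.

Two output modes:

* feature mode — draw lesion feature vectors directly (fast; the primary test
  surface), and
* volume mode — synthesize a small SUV-like 3-D volume plus binary VOI mask
  per lesion (a correlated Gaussian random field inside an ellipsoid), so the
  radiomic extractor can be exercised end to end.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .cohort import (ADT_STATES, SITE_CLASSES, TREATMENTS, CohortTable)
from .errors import ConfigurationError, DegenerateVOIError

_PROB_TOL = 1e-9


def _default_count_law() -> dict[int, float]:
    # Mix of single- and multi-lesion patients: ~40% single-lesion, mean ~4
    # lesions/patient, heavy right tail up to 20.
    return {1: 0.40, 2: 0.07, 3: 0.06, 4: 0.08, 5: 0.08, 6: 0.08, 7: 0.07,
            8: 0.06, 10: 0.05, 12: 0.03, 15: 0.015, 20: 0.005}


def _default_site_probs() -> dict[str, float]:
    # Regional LN / distant LN / bone mix typical of recurrent PCa.
    return {"REGIONAL_LN": 68 / 370, "DISTANT_LN": 81 / 370,
            "BONE": 221 / 370}


def _default_suv_law() -> dict[str, tuple[float, float]]:
    # Per-site lognormal (mu, sigma) of SUVmax; bone lesions run hotter.
    return {"REGIONAL_LN": (np.log(4.5), 0.45),
            "DISTANT_LN": (np.log(5.0), 0.45),
            "BONE": (np.log(6.0), 0.55)}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort.

    Attributes
    ----------
    n_patients : number of patients.
    lesion_count_law : categorical law over per-patient lesion counts
        (count -> probability); support must be positive integers.
    site_probs : probability of each anatomical site class per lesion.
    n_archetypes : number of latent phenotype archetypes shared by the
        cohort.  ``n_archetypes == n_patients`` gives every patient a
        private archetype.
    sigma_between : s.d. of archetype means per feature axis.
    sigma_within : s.d. of within-patient lesion noise per feature axis.
    sigma_within_slope : relative growth of ``sigma_within`` per lesion
        beyond the first (``sigma_within * (1 + slope*(n-1))``); models
        cohorts in which high-burden patients carry more heterogeneous
        lesions.  0 disables.
    site_effect_scale : magnitude of the additive per-site feature shift.
    suv_law : per-site lognormal ``(mu, sigma)`` parameters of SUVmax.
    metabolic_factor_weight : fraction of within-patient feature variance
        carried by a shared latent "metabolic" factor (radiomic features are
        strongly inter-correlated in practice; this emulates that).  0 gives
        purely spherical within-patient noise.
    suv_phenotype_coupling : shift of log-SUVmax per standardized unit of a
        lesion's metabolic-factor score; couples a lesion's metabolism to its
        own texture phenotype, so SUV-similar lesions are also
        feature-similar.  0 disables.
    psa_burden_coupling : slope of log-PSA on log lesion count; makes
        high-burden patients present with higher PSA.  0 disables.
    n_features : dimensionality of the synthetic feature space.
    seed : RNG seed; all randomness flows from it.
    """

    n_patients: int = 92
    lesion_count_law: dict[int, float] = field(default_factory=_default_count_law)
    site_probs: dict[str, float] = field(default_factory=_default_site_probs)
    n_archetypes: int = 8
    sigma_between: float = 1.0
    sigma_within: float = 1.0
    sigma_within_slope: float = 0.0
    site_effect_scale: float = 0.5
    suv_law: dict[str, tuple[float, float]] = field(default_factory=_default_suv_law)
    metabolic_factor_weight: float = 0.3
    suv_phenotype_coupling: float = 0.8
    psa_burden_coupling: float = 0.6
    n_features: int = 42
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.n_archetypes < 1:
            raise ConfigurationError("n_archetypes must be >= 1")
        if self.sigma_between < 0:
            raise ConfigurationError("sigma_between must be >= 0")
        if self.sigma_within < 0:
            raise ConfigurationError("sigma_within must be >= 0")
        if self.site_effect_scale < 0:
            raise ConfigurationError("site_effect_scale must be >= 0")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if not 0 <= self.metabolic_factor_weight < 1:
            raise ConfigurationError(
                "metabolic_factor_weight must be in [0, 1)")
        if abs(sum(self.lesion_count_law.values()) - 1.0) > _PROB_TOL:
            raise ConfigurationError("lesion_count_law probabilities must sum to 1")
        if any((not float(k).is_integer()) or k < 1 for k in self.lesion_count_law):
            raise ConfigurationError("lesion_count_law support must be integers >= 1")
        if set(self.site_probs) != set(SITE_CLASSES):
            raise ConfigurationError(f"site_probs keys must be {SITE_CLASSES}")
        if abs(sum(self.site_probs.values()) - 1.0) > _PROB_TOL:
            raise ConfigurationError("site_probs must sum to 1")
        if set(self.suv_law) != set(SITE_CLASSES):
            raise ConfigurationError(f"suv_law keys must be {SITE_CLASSES}")


@dataclass
class SyntheticCohort:
    """A generated cohort: clinical tables, feature table, ground truth, and
    (in volume mode) per-lesion image/mask pairs."""

    cohort_table: CohortTable
    feature_table: pd.DataFrame
    truth: dict
    volumes: dict[str, tuple[np.ndarray, np.ndarray, float]] | None = None


def _feature_names(n: int) -> list[str]:
    if n == 42:
        from .features import DEFAULT_ROSTER
        return list(DEFAULT_ROSTER)
    return [f"f{i:02d}" for i in range(n)]


def generate_feature_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort directly in feature space.

    Per patient: archetype ``a(p)`` uniform over archetypes, lesion count from
    ``lesion_count_law``, clinical covariates.  Per lesion: feature vector =
    archetype mean + site effect + spherical Gaussian within-patient noise;
    SUVmax lognormal per site (optionally phenotype-coupled).  Fully
    reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    d = config.n_features

    arch_means = rng.normal(0.0, config.sigma_between,
                            size=(config.n_archetypes, d))
    site_dirs = rng.normal(size=(len(SITE_CLASSES), d))
    site_dirs /= np.linalg.norm(site_dirs, axis=1, keepdims=True)
    metab_axis = rng.normal(size=d)
    metab_axis /= np.linalg.norm(metab_axis)
    site_effects = {s: config.site_effect_scale * site_dirs[i]
                    for i, s in enumerate(SITE_CLASSES)}

    counts_support = np.array(sorted(config.lesion_count_law), dtype=int)
    counts_p = np.array([config.lesion_count_law[int(k)] for k in counts_support])
    counts_p = counts_p / counts_p.sum()
    site_names = list(SITE_CLASSES)
    site_p = np.array([config.site_probs[s] for s in site_names])
    site_p = site_p / site_p.sum()

    # When archetypes are at least as numerous as patients, each patient
    # gets a private archetype (sampling without replacement); otherwise
    # archetypes are shared uniformly at random.
    if config.n_archetypes >= config.n_patients:
        arch_ids = rng.permutation(config.n_archetypes)[:config.n_patients]
    else:
        arch_ids = rng.integers(config.n_archetypes, size=config.n_patients)

    patients, lesions, feat_rows = [], [], []
    latents = []
    archetype_of = {}
    for ip in range(config.n_patients):
        pid = f"P{ip + 1:03d}"
        a = int(arch_ids[ip])
        archetype_of[pid] = a
        n_les = int(rng.choice(counts_support, p=counts_p))
        age = float(np.clip(rng.normal(72.0, 7.0), 55.0, 85.0))
        gleason = int(rng.choice([5, 6, 7, 8, 9],
                                 p=[0.03, 0.15, 0.45, 0.25, 0.12]))
        log_psa = (np.log(2.7) + config.psa_burden_coupling * np.log(n_les)
                   + rng.normal(0.0, 1.3))
        adt = ADT_STATES[0] if rng.random() < 0.36 else ADT_STATES[1]
        treatment = str(rng.choice(TREATMENTS, p=[0.25, 0.565, 0.098, 0.087]))
        patients.append({"patient_id": pid, "age": round(age, 1),
                         "gleason": gleason,
                         "psa_ng_ml": round(float(np.exp(log_psa)), 3),
                         "adt_status": adt, "primary_treatment": treatment})

        sw = config.sigma_within * (1.0 + config.sigma_within_slope * (n_les - 1))
        for il in range(n_les):
            lid = f"{pid}_L{il + 1:02d}"
            site = site_names[int(rng.choice(len(site_names), p=site_p))]
            latent = arch_means[a] + site_effects[site]
            rho = config.metabolic_factor_weight
            g = float(rng.normal())
            noise = sw * (np.sqrt(1 - rho) * rng.normal(size=d)
                          + np.sqrt(rho * d) * g * metab_axis)
            vec = latent + noise
            metab_score = g
            mu, sg = config.suv_law[site]
            suv = float(np.exp(mu
                               + config.suv_phenotype_coupling * metab_score
                               + rng.normal(0.0, sg)))
            lesions.append({"lesion_id": lid, "patient_id": pid,
                            "site_class": site, "suv_max": round(suv, 3)})
            feat_rows.append(vec)
            latents.append(latent)

    cohort = CohortTable(pd.DataFrame(patients), pd.DataFrame(lesions))
    names = _feature_names(d)
    feature_table = pd.concat(
        [cohort.lesions.reset_index(drop=True),
         pd.DataFrame(np.asarray(feat_rows), columns=names)], axis=1)
    truth = {"patient_archetype": pd.Series(archetype_of, name="archetype"),
             "lesion_latent": np.asarray(latents),
             "archetype_means": arch_means}
    return SyntheticCohort(cohort, feature_table, truth)


@dataclass
class TextureArchetype:
    """Texture law of a lesion phenotype: mean SUV, voxelwise s.d. and
    spatial correlation length of a clipped Gaussian random field."""

    mean_suv: float = 5.0
    texture_sd: float = 1.0
    correlation_length_mm: float = 4.0


def generate_lesion_volume(archetype_texture: TextureArchetype,
                           site: str,
                           radius_mm: float | tuple[float, float, float],
                           spacing_mm: float = 2.0,
                           seed: int = 0,
                           margin_voxels: int = 2,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one lesion: an SUV-like volume and its ellipsoidal mask.

    The in-mask signal is a correlated Gaussian random field (white noise
    smoothed to the archetype's correlation length, rescaled to its texture
    s.d.) around the archetype's mean SUV, clipped at 0; the background is
    near-zero noise.  Returns ``(volume, mask)`` on the same grid at
    ``spacing_mm`` isotropic.
    """
    if site not in SITE_CLASSES:
        raise ConfigurationError(f"site must be one of {SITE_CLASSES}")
    radii = np.broadcast_to(np.asarray(radius_mm, dtype=float), (3,)).copy()
    if np.any(radii <= 0) or spacing_mm <= 0:
        raise ConfigurationError("radius_mm and spacing_mm must be positive")
    half = np.floor(radii / spacing_mm).astype(int)
    # need >= 3 voxels across the mask in every axis
    if np.any(2 * half + 1 < 3):
        raise DegenerateVOIError(
            f"mask spans fewer than 3 voxels in some axis at spacing "
            f"{spacing_mm} mm (radii {tuple(radii)} mm)")
    shape = tuple(2 * (half + margin_voxels) + 1)
    center = (np.array(shape) - 1) / 2.0
    idx = np.indices(shape, dtype=float)
    dist2 = sum(((idx[k] - center[k]) * spacing_mm / radii[k]) ** 2
                for k in range(3))
    mask = (dist2 <= 1.0).astype(np.uint8)

    rng = np.random.default_rng(seed)
    noise = rng.normal(size=shape)
    sigma_vox = archetype_texture.correlation_length_mm / spacing_mm
    if sigma_vox > 0:
        field_ = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    else:
        field_ = noise
    sd = field_.std()
    if archetype_texture.texture_sd > 0 and sd > 0:
        field_ = field_ / sd * archetype_texture.texture_sd
    else:
        field_ = np.zeros(shape)
    volume = np.where(mask == 1,
                      archetype_texture.mean_suv + field_,
                      np.abs(rng.normal(0.0, 0.05, size=shape)))
    return np.clip(volume, 0.0, None), mask


def generate_volume_cohort(config: SyntheticConfig,
                           spacing_mm: float = 2.0,
                           radius_law: tuple[float, float] = (np.log(8.0), 0.25),
                           ) -> SyntheticCohort:
    """Feature-mode cohort plus one synthetic volume/mask pair per lesion.

    Each archetype gets its own texture law (mean SUV, variance, correlation
    length drawn once from the seed), so lesions of different archetypes are
    texturally separable; lesion radii follow a lognormal law (mm).
    The returned ``feature_table`` still holds the latent feature draws; run
    the extractor over ``volumes`` to obtain image-derived features.
    """
    cohort = generate_feature_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    textures = [TextureArchetype(
        mean_suv=float(rng.uniform(3.0, 8.0)),
        texture_sd=float(rng.uniform(0.4, 1.6)),
        correlation_length_mm=float(rng.uniform(1.0, 5.0)))
        for _ in range(config.n_archetypes)]
    volumes = {}
    arch = cohort.truth["patient_archetype"]
    for _, row in cohort.cohort_table.lesions.iterrows():
        lid = row["lesion_id"]
        a = int(arch[row["patient_id"]])
        radius = float(np.clip(rng.lognormal(*radius_law), 5.0, 18.0))
        vol, mask = generate_lesion_volume(
            textures[a], row["site_class"], radius, spacing_mm,
            seed=int(rng.integers(2 ** 31)))
        volumes[lid] = (vol, mask, spacing_mm)
        # keep tabular SUVmax consistent with the image (max in-mask voxel)
        suv = float(vol[mask == 1].max())
        for tbl in (cohort.cohort_table.lesions, cohort.feature_table):
            tbl.loc[tbl["lesion_id"] == lid, "suv_max"] = round(suv, 3)
    cohort.volumes = volumes
    cohort.truth["archetype_textures"] = textures
    return cohort


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write a cohort to ``directory``: tables as CSV, volumes as NIfTI, and
    a YAML manifest listing every file with its sha256 checksum.  Returns the
    manifest dict."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[dict] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        p = directory / name
        df.to_csv(p, index=False)
        files.append({"path": name, "sha256": _sha256(p)})

    _write_csv(cohort.cohort_table.patients, "patients.csv")
    _write_csv(cohort.cohort_table.lesions, "lesions.csv")
    if cohort.feature_table is not None:
        _write_csv(cohort.feature_table, "features.csv")

    lesion_entries = []
    if cohort.volumes:
        vdir = directory / "volumes"
        vdir.mkdir(exist_ok=True)
        for lid, (vol, mask, spacing) in cohort.volumes.items():
            affine = np.diag([spacing, spacing, spacing, 1.0])
            for arr, suffix in ((vol.astype(np.float32), "suv"),
                                (mask.astype(np.uint8), "mask")):
                rel = f"volumes/{lid}_{suffix}.nii.gz"
                nib.save(nib.Nifti1Image(arr, affine), directory / rel)
                files.append({"path": rel, "sha256": _sha256(directory / rel)})
            lesion_entries.append({"lesion_id": lid,
                                   "volume": f"volumes/{lid}_suv.nii.gz",
                                   "mask": f"volumes/{lid}_mask.nii.gz"})
    manifest = {"n_patients": cohort.cohort_table.n_patients,
                "n_lesions": cohort.cohort_table.n_lesions,
                "lesions": lesion_entries,
                "files": files}
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return manifest
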