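"""Synthetic cohort and phantom image generator.

Emulates the three study populations the referral classifier is developed
on: a high-prevalence lesion cohort, a healthy-volunteer cohort, and a
low-prevalence deployment cohort (a community dental-clinic population with
roughly 3% referral sites).  Each site receives paired white-light (WL) and
autofluorescence (AF) phantom images with a mucosa annotation mask.

The phantoms are parametric: the mucosa is a noisy textured ellipse on a
dark background; referral sites additionally carry a lesion ellipse that is
brighter/whiter in WL and shows loss of green fluorescence in AF — the
optical signature the real instrument looks for.  The generator records the
painted lesion footprint in ``lesion_mask`` as internal ground truth.

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .records import (
    ANATOMIC_LABELS,
    COHORTS,
    RISK_FIELDS,
    ImagePair,
    PatientRecord,
    SiteRecord,
)

# Category vocabularies and sampling probabilities, patterned on a community
# dental-clinic population (majority female, ethnically mixed, ~14% smokers).
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "gender": {"female": 0.52, "male": 0.48},
    "ethnicity": {"hispanic": 0.46, "not_hispanic": 0.54},
    "race": {"asian": 0.17, "black": 0.37, "white": 0.46},
    "cigarette": {"yes": 0.14, "no": 0.86},
    "smoking_tobacco": {"yes": 0.14, "no": 0.86},
    "smokeless_tobacco": {"yes": 0.04, "no": 0.96},
    "alcohol": {"yes": 0.54, "no": 0.46},
}

MANIFEST_COLUMNS = [
    "patient_id",
    "site_id",
    "capture_id",
    "cohort",
    "anatomic_label",
    "referral_label",
    "contralateral_normal",
    "qc_fail",
    "wl_path",
    "af_path",
    "mask_path",
    "lesion_path",
    "age",
    *RISK_FIELDS,
]


@dataclass
class LesionEffect:
    """Contrast parameters of the painted lesion phenotype.

    wl_contrast: blend fraction toward a pale keratotic color in WL.
    af_loss: multiplicative loss of green-channel fluorescence in AF.
    """

    wl_contrast: float = 0.4
    af_loss: float = 0.55


@dataclass
class CohortConfig:
    """Configuration for one synthetic cohort.

    Referral labels default to per-site Bernoulli draws at
    ``refer_prevalence``; the ``exact_*`` fields pin exact label counts so a
    cohort can reproduce a published dataset shape deterministically.
    """

    cohort: str
    n_patients: int
    sites_per_patient: int = 5
    n_extra_sites: int = 0
    refer_prevalence: float = 0.0
    refer_other_fraction: float = 0.0
    exact_refer_sites: Optional[int] = None
    exact_refer_other: Optional[int] = None
    exact_contralateral: Optional[int] = None
    n_qc_fail_sites: int = 0
    captures_per_site: tuple[int, int] = (1, 2)
    missingness: dict[str, float] = field(default_factory=dict)
    demographics: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    )
    age_range: tuple[float, float] = (18.0, 90.0)
    age_mean: float = 49.2
    age_sd: float = 15.1
    image_size: int = 256
    lesion_effect: LesionEffect = field(default_factory=LesionEffect)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.n_patients <= 0 or self.sites_per_patient <= 0:
            raise ValueError("n_patients and sites_per_patient must be positive")
        for name in ("refer_prevalence", "refer_other_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for f_, r in self.missingness.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate for {f_} must lie in [0, 1]")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        lo, hi = self.captures_per_site
        if not 1 <= lo <= hi:
            raise ValueError("captures_per_site must be an increasing range >= 1")


def _prefix(cohort: str) -> str:
    return {"high_prevalence": "H", "healthy": "V", "low_prevalence": "L"}[cohort]


def _draw_age(cfg: CohortConfig, rng: np.random.Generator) -> float:
    lo, hi = cfg.age_range
    for _ in range(100):
        a = rng.normal(cfg.age_mean, cfg.age_sd)
        if lo <= a <= hi:
            return float(round(a, 1))
    return float((lo + hi) / 2)


def _draw_category(probs: dict[str, float], rng: np.random.Generator) -> str:
    cats = sorted(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    return cats[rng.choice(len(cats), p=p / p.sum())]


def generate_cohort(config: CohortConfig) -> tuple[list[PatientRecord], list[SiteRecord]]:
    """Generate one cohort of patients and labeled sites (no images yet).

    Deterministic given ``config.seed``.  Referral sites are placed
    patient-first (a lesion patient presents with a primary lesion site;
    additional lesions overflow onto further sites of already-lesioned
    patients), which concentrates referrals in a realistic number of
    patients.  Contralateral-normal flags are produced only in the
    high-prevalence cohort, where clinically normal mirror sites of lesion
    patients are imaged as internal controls.
    """
    rng = np.random.default_rng(config.seed)
    pre = _prefix(config.cohort)

    patients = []
    for i in range(config.n_patients):
        patients.append(
            PatientRecord(
                patient_id=f"{pre}{i:04d}",
                cohort=config.cohort,
                age=_draw_age(config, rng),
                **{f_: _draw_category(config.demographics[f_], rng) for f_ in RISK_FIELDS},
            )
        )

    # site counts: base count per patient, extras dealt one-per-patient in
    # seeded shuffled order
    counts = np.full(config.n_patients, config.sites_per_patient, dtype=int)
    if config.n_extra_sites:
        order = rng.permutation(config.n_patients)
        for k in range(config.n_extra_sites):
            counts[order[k % config.n_patients]] += 1

    sites: list[SiteRecord] = []
    sites_by_patient: dict[str, list[int]] = {}
    for pi, patient in enumerate(patients):
        labels = list(rng.permutation(np.array(ANATOMIC_LABELS[:5])))
        for si in range(counts[pi]):
            label = labels[si] if si < 5 else "other"
            idx = len(sites)
            sites.append(
                SiteRecord(
                    site_id=f"{patient.patient_id}-S{si}",
                    patient_id=patient.patient_id,
                    cohort=config.cohort,
                    anatomic_label=str(label),
                    referral_label="do_not_refer",
                )
            )
            sites_by_patient.setdefault(patient.patient_id, []).append(idx)

    _assign_referrals(sites, sites_by_patient, config, rng)
    _flag_contralaterals(sites, sites_by_patient, config, rng)
    _mark_qc_failures(sites, sites_by_patient, config, rng)

    for site in sites:
        n_cap = int(rng.integers(config.captures_per_site[0], config.captures_per_site[1] + 1))
        site.image_pair_ids = [f"{site.site_id}-c{k}" for k in range(n_cap)]

    patients = inject_missingness(patients, config.missingness, rng)
    return patients, sites


def _assign_referrals(sites, sites_by_patient, config, rng) -> None:
    n_sites = len(sites)
    if config.exact_refer_sites is not None:
        n_refer = config.exact_refer_sites
        if n_refer > n_sites:
            raise ValueError("exact_refer_sites exceeds number of sites")
        pids = list(rng.permutation(sorted(sites_by_patient)))
        chosen: list[int] = []
        # primary lesion site for each lesion patient
        for pid in pids[: min(n_refer, len(pids))]:
            chosen.append(sites_by_patient[pid][0])
        # overflow lesions land on further sites of already-lesioned patients
        overflow = n_refer - len(chosen)
        if overflow > 0:
            pool = [
                idx
                for pid in pids
                for idx in sites_by_patient[pid][1:]
                if sites_by_patient[pid][0] in chosen
            ]
            if overflow > len(pool):
                raise ValueError("not enough sites to place exact_refer_sites lesions")
            chosen.extend(rng.choice(np.array(pool), size=overflow, replace=False).tolist())
        refer_idx = np.array(sorted(chosen))
    else:
        draws = rng.random(n_sites) < config.refer_prevalence
        refer_idx = np.flatnonzero(draws)

    for idx in refer_idx:
        sites[idx].referral_label = "refer_suspicion"

    if len(refer_idx):
        if config.exact_refer_other is not None:
            n_other = config.exact_refer_other
            if n_other > len(refer_idx):
                raise ValueError("exact_refer_other exceeds number of referral sites")
        else:
            n_other = int(round(config.refer_other_fraction * len(refer_idx)))
        for idx in rng.choice(refer_idx, size=n_other, replace=False):
            sites[idx].referral_label = "refer_other"


def _flag_contralaterals(sites, sites_by_patient, config, rng) -> None:
    if config.cohort != "high_prevalence":
        return
    eligible: list[int] = []  # one candidate normal site per lesion patient
    for pid in sorted(sites_by_patient):
        idxs = sites_by_patient[pid]
        has_lesion = any(sites[i].is_referral for i in idxs)
        normals = [i for i in idxs if not sites[i].is_referral]
        if has_lesion and normals:
            eligible.append(normals[int(rng.integers(len(normals)))])
    if config.exact_contralateral is not None:
        if config.exact_contralateral > len(eligible):
            raise ValueError(
                f"exact_contralateral={config.exact_contralateral} but only "
                f"{len(eligible)} lesion patients have a normal site"
            )
        eligible = rng.choice(np.array(eligible), size=config.exact_contralateral, replace=False).tolist()
    for idx in eligible:
        sites[idx].contralateral_normal = True


def _mark_qc_failures(sites, sites_by_patient, config, rng) -> None:
    """Mark sites whose captures will miss the AF frame (QC failures)."""
    if not config.n_qc_fail_sites:
        return
    pool = [i for i, s in enumerate(sites) if not s.is_referral]
    if config.n_qc_fail_sites > len(pool):
        raise ValueError("n_qc_fail_sites exceeds number of non-referral sites")
    for idx in rng.choice(np.array(pool), size=config.n_qc_fail_sites, replace=False):
        sites[idx].qc_fail = True


def inject_missingness(
    patients: Sequence[PatientRecord],
    rates: dict[str, float],
    rng_state: np.random.Generator | int | None = None,
) -> list[PatientRecord]:
    """Blank each risk-factor field independently at its configured rate."""
    rng = (
        rng_state
        if isinstance(rng_state, np.random.Generator)
        else np.random.default_rng(rng_state)
    )
    for f_, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"missingness rate for {f_} must lie in [0, 1]")
    out = []
    for p in patients:
        updates = {}
        for f_ in ("age", *RISK_FIELDS):
            r = rates.get(f_, 0.0)
            if r and rng.random() < r:
                updates[f_] = None
        out.append(replace(p, **updates) if updates else p)
    return out


# ---------------------------------------------------------------------------
# phantom rendering
# ---------------------------------------------------------------------------

WL_BG, WL_MUCOSA = np.array([18.0, 14.0, 14.0]), np.array([186.0, 122.0, 116.0])
WL_LESION_TARGET = np.array([235.0, 222.0, 210.0])
AF_BG, AF_MUCOSA = np.array([8.0, 12.0, 10.0]), np.array([40.0, 165.0, 70.0])


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def render_image_pair(
    site: SiteRecord,
    config: CohortConfig,
    rng_state: np.random.Generator | None = None,
    capture_index: int = 0,
) -> ImagePair:
    """Render the WL/AF/mask raster triplet for one capture of a site.

    The capture-specific RNG stream is derived from the cohort seed and the
    capture id, so rasters are bit-identical across runs and independent of
    rendering order.
    """
    if config.image_size < 32:
        raise ValueError("image_size must be at least 32")
    if capture_index >= len(site.image_pair_ids):
        raise ValueError(f"site {site.site_id} has no capture {capture_index}")
    capture_id = site.image_pair_ids[capture_index]
    if rng_state is None:
        rng_state = np.random.default_rng(
            np.random.SeedSequence([config.seed & 0x7FFFFFFF, zlib.crc32(capture_id.encode())])
        )
    rng = rng_state
    n = config.image_size

    cy = n / 2 + rng.uniform(-0.05, 0.05) * n
    cx = n / 2 + rng.uniform(-0.05, 0.05) * n
    ry = rng.uniform(0.28, 0.40) * n
    rx = rng.uniform(0.28, 0.40) * n
    mask = _ellipse_mask(n, n, cy, cx, ry, rx)

    texture = gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=n / 16.0)
    texture /= max(texture.std(), 1e-9)

    wl = np.empty((n, n, 3))
    af = np.empty((n, n, 3))
    for c in range(3):
        wl[..., c] = np.where(mask, WL_MUCOSA[c], WL_BG[c]) + rng.normal(0, 6, (n, n))
        af[..., c] = np.where(mask, AF_MUCOSA[c], AF_BG[c]) + rng.normal(0, 5, (n, n))
        wl[..., c] += np.where(mask, texture * 10.0, 0.0)
    af[..., 1] += np.where(mask, texture * 8.0, 0.0)

    lesion_mask = np.zeros((n, n), dtype=bool)
    if site.is_referral:
        theta = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.0, 0.45)
        lcy = cy + rad * ry * np.sin(theta)
        lcx = cx + rad * rx * np.cos(theta)
        lry = rng.uniform(0.18, 0.30) * ry
        lrx = rng.uniform(0.18, 0.30) * rx
        lesion_mask = _ellipse_mask(n, n, lcy, lcx, lry, lrx) & mask
        c_wl = config.lesion_effect.wl_contrast
        wl[lesion_mask] = wl[lesion_mask] * (1 - c_wl) + WL_LESION_TARGET * c_wl
        loss = config.lesion_effect.af_loss
        af[lesion_mask, 1] *= 1 - loss
        af[lesion_mask, 2] *= 1 - 0.5 * loss

    wl8 = np.clip(wl, 0, 255).astype(np.uint8)
    af8 = np.clip(af, 0, 255).astype(np.uint8)
    pair = ImagePair(
        capture_id=capture_id,
        wl=wl8,
        af=None if site.qc_fail else af8,
        mask=mask,
        lesion_mask=lesion_mask,
    )
    pair.validate()
    return pair


def render_cohort(
    sites: Sequence[SiteRecord], config: CohortConfig
) -> dict[str, ImagePair]:
    """Render every capture of every site; keyed by capture id."""
    pairs: dict[str, ImagePair] = {}
    for site in sites:
        for k in range(len(site.image_pair_ids)):
            pair = render_image_pair(site, config, capture_index=k)
            pairs[pair.capture_id] = pair
    return pairs


# ---------------------------------------------------------------------------
# on-disk cohort layout
# ---------------------------------------------------------------------------


def write_cohort(
    dir_path: str | Path,
    patients: Sequence[PatientRecord],
    sites: Sequence[SiteRecord],
    image_pairs: dict[str, ImagePair],
) -> Path:
    """Write PNG rasters and a manifest CSV; returns the manifest path."""
    root = Path(dir_path)
    img_dir = root / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    patients_by_id = {p.patient_id: p for p in patients}

    rows = []
    for site in sites:
        patient = patients_by_id[site.patient_id]
        for capture_id in site.image_pair_ids:
            pair = image_pairs[capture_id]
            paths = {}
            for kind, arr in (
                ("wl", pair.wl),
                ("af", pair.af),
                ("mask", (pair.mask.astype(np.uint8) * 255)),
                ("lesion", (pair.lesion_mask.astype(np.uint8) * 255)),
            ):
                if arr is None:
                    paths[kind] = ""
                    continue
                rel = f"images/{capture_id}_{kind}.png"
                iio.imwrite(root / rel, arr)
                paths[kind] = rel
            rows.append(
                {
                    "patient_id": site.patient_id,
                    "site_id": site.site_id,
                    "capture_id": capture_id,
                    "cohort": site.cohort,
                    "anatomic_label": site.anatomic_label,
                    "referral_label": site.referral_label,
                    "contralateral_normal": site.contralateral_normal,
                    "qc_fail": bool(site.qc_fail),
                    "wl_path": paths["wl"],
                    "af_path": paths["af"],
                    "mask_path": paths["mask"],
                    "lesion_path": paths["lesion"],
                    "age": patient.age,
                    **{f_: getattr(patient, f_) for f_ in RISK_FIELDS},
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = root / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(
    manifest_path: str | Path, load_images: bool = True
) -> tuple[list[PatientRecord], list[SiteRecord], dict[str, ImagePair]]:
    """Reload a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path, keep_default_na=False, na_values=[""])

    patients: dict[str, PatientRecord] = {}
    sites: dict[str, SiteRecord] = {}
    pairs: dict[str, ImagePair] = {}
    for _, row in df.iterrows():
        pid = row["patient_id"]
        if pid not in patients:
            patients[pid] = PatientRecord(
                patient_id=pid,
                cohort=row["cohort"],
                age=None if pd.isna(row["age"]) else float(row["age"]),
                **{
                    f_: (None if pd.isna(row[f_]) else str(row[f_]))
                    for f_ in RISK_FIELDS
                },
            )
        sid = row["site_id"]
        if sid not in sites:
            site = SiteRecord(
                site_id=sid,
                patient_id=pid,
                cohort=row["cohort"],
                anatomic_label=row["anatomic_label"],
                referral_label=row["referral_label"],
                contralateral_normal=bool(row["contralateral_normal"]),
            )
            site.qc_fail = bool(row["qc_fail"])
            sites[sid] = site
        sites[sid].image_pair_ids.append(row["capture_id"])
        if load_images:
            def _read(rel, as_mask=False):
                if not rel or pd.isna(rel):
                    return None
                arr = iio.imread(root / rel)
                return arr > 127 if as_mask else arr

            mask = _read(row["mask_path"], as_mask=True)
            lesion = _read(row["lesion_path"], as_mask=True)
            pairs[row["capture_id"]] = ImagePair(
                capture_id=row["capture_id"],
                wl=_read(row["wl_path"]),
                af=_read(row["af_path"]),
                mask=mask,
                lesion_mask=lesion if lesion is not None else np.zeros_like(mask),
            )
    return list(patients.values()), list(sites.values()), pairs
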