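"""Synthetic multi-site chest-radiograph-like study sets.

The generator produces the statistical structure the analysis pipeline
assumes, with no real patient data: several "hospital systems" whose images
carry site-detectable acquisition artifacts (a bright corner metal token, a
near-white text banner, department-specific intensity inversion, background
offsets), a genuine diffuse disease signal (a soft elliptical opacity in
the lung fields of pneumonia-positive frontal studies), per-site disease
prevalence assigned as an exact count, patients with multiple studies,
sex/age metadata, and templated free-text reports from which labels can be
re-inferred.

Everything downstream of a (config, profiles, seed) triple is reproducible
bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FINDINGS = (
    "cardiomegaly",
    "emphysema",
    "effusion",
    "hernia",
    "nodule",
    "atelectasis",
    "pneumonia",
    "edema",
    "consolidation",
)

# marginal rates for the eight findings without a rendered image signal;
# loosely shaped like a general-hospital case mix
DEFAULT_FINDING_RATES = {
    "cardiomegaly": 0.06,
    "emphysema": 0.02,
    "effusion": 0.12,
    "hernia": 0.02,
    "nodule": 0.05,
    "atelectasis": 0.10,
    "edema": 0.03,
    "consolidation": 0.05,
}


@dataclass
class TokenSpec:
    """Corner metal-token blob: bright square blended in with max()."""

    corner: str = "top_left"  # top_left|top_right|bottom_left|bottom_right
    side: int = 6
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.corner not in ("top_left", "top_right", "bottom_left", "bottom_right"):
            raise ValueError(f"unknown corner {self.corner!r}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("token intensity must be in [0, 1]")


@dataclass
class BannerSpec:
    """Rows of near-white pixels (with dark text-like dashes) at an edge."""

    edge: str = "top"  # top|bottom
    rows: int = 4
    intensity: float = 0.96

    def __post_init__(self) -> None:
        if self.edge not in ("top", "bottom"):
            raise ValueError(f"unknown edge {self.edge!r}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("banner intensity must be in [0, 1]")


@dataclass
class SiteProfile:
    """Acquisition profile of one hospital system."""

    site_id: str
    prevalence: float
    department_mix: dict[str, float] = field(default_factory=lambda: {"inpatient": 1.0})
    token: TokenSpec | None = None
    banner: BannerSpec | None = None
    invert_by_department: dict[str, bool] = field(default_factory=dict)
    background_offset: float = 0.0
    noise_sd: float = 0.06
    sex_female_fraction: float = 0.5
    age_mean_sd: tuple[float, float] = (55.0, 16.0)

    def __post_init__(self) -> None:
        total = sum(self.department_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"department mix sums to {total}, not 1")
        for name, value in [
            ("prevalence", self.prevalence),
            ("sex_female_fraction", self.sex_female_fraction),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GeneratorConfig:
    patients_per_site: int | dict[str, int] = 200
    studies_per_patient_mean: float = 3.5
    max_studies_per_patient: int = 10
    image_size: int = 64
    effect_size: float = 0.15  # amplitude of the pneumonia opacity
    disease_persistence: float = 0.6  # P(another study of an affected patient is positive)
    lateral_fraction: float = 0.12
    make_reports: bool = False
    render_images: bool = True  # metadata-only sets are cheap for sampler work
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.patients_per_site.values()
            if isinstance(self.patients_per_site, dict)
            else [self.patients_per_site]
        )
        if any(c <= 0 for c in counts):
            raise ValueError("patient counts must be positive")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.image_size % 8 != 0:
            raise ValueError("image size must be divisible by 8")

    def n_patients(self, site_id: str) -> int:
        if isinstance(self.patients_per_site, dict):
            return self.patients_per_site[site_id]
        return self.patients_per_site


@dataclass
class StudyRecord:
    patient_id: str
    study_id: str
    site_id: str
    department: str
    view: str  # frontal|lateral
    sex: str  # F|M
    age: float
    labels: dict[str, int]
    image: np.ndarray | None = None
    report: str | None = None


# ---------------------------------------------------------------------------
# Image rendering


def _ellipse_mask(size: int, cr: float, cc: float, rr: float, rc: float) -> np.ndarray:
    r, c = np.ogrid[:size, :size]
    return ((r - cr) / rr) ** 2 + ((c - cc) / rc) ** 2 <= 1.0


def lung_field_masks(size: int, view: str) -> list[np.ndarray]:
    """Interior regions in which disease opacities may be placed."""
    s = size
    if view == "frontal":
        return [
            _ellipse_mask(s, 0.47 * s, 0.32 * s, 0.27 * s, 0.14 * s),
            _ellipse_mask(s, 0.47 * s, 0.66 * s, 0.27 * s, 0.14 * s),
        ]
    return [_ellipse_mask(s, 0.48 * s, 0.52 * s, 0.28 * s, 0.20 * s)]


def _render_anatomy(size: int, view: str) -> np.ndarray:
    s = size
    img = np.full((s, s), 0.08, dtype=np.float64)  # air outside the body
    if view == "frontal":
        body = _ellipse_mask(s, 0.52 * s, 0.49 * s, 0.46 * s, 0.40 * s)
        img[body] = 0.55
        for lung in lung_field_masks(s, view):
            img[lung] = 0.28
        # spine / mediastinal stripe
        img[:, int(0.46 * s) : int(0.54 * s)] = np.maximum(
            img[:, int(0.46 * s) : int(0.54 * s)], 0.60
        )
    else:
        # lateral: shifted silhouette, single lung field, bright posterior spine
        body = _ellipse_mask(s, 0.52 * s, 0.55 * s, 0.46 * s, 0.33 * s)
        img[body] = 0.55
        for lung in lung_field_masks(s, view):
            img[lung] = 0.30
        col0, col1 = int(0.78 * s), int(0.86 * s)
        img[int(0.1 * s) : int(0.95 * s), col0:col1] = 0.68
    return img


def render_image(
    view: str,
    department: str,
    pneumonia: int,
    profile: SiteProfile,
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> np.ndarray:
    """Render one grayscale study image in [0, 1].

    Random draws happen in a fixed order regardless of the pneumonia label,
    so with effect size 0 a positive and a negative study rendered from
    identical generator states are pixel-identical. Inversion (1 - pixel)
    applies to anatomy, disease and noise; the token and banner are drawn
    on top afterwards, as archive overlays are.
    """
    s = config.image_size
    img = _render_anatomy(s, view)
    img += profile.background_offset
    img += rng.normal(0.0, profile.noise_sd, size=(s, s))

    # disease opacity: always drawn, scaled by label * effect size
    lungs = lung_field_masks(s, view)
    lung = lungs[int(rng.integers(len(lungs)))]
    rows, cols = np.nonzero(lung)
    pick = int(rng.integers(len(rows)))
    cr, cc = rows[pick], cols[pick]
    rr = rng.uniform(0.06 * s, 0.12 * s)
    rc = rng.uniform(0.06 * s, 0.12 * s)
    amplitude = config.effect_size * (pneumonia if view == "frontal" else 0)
    if amplitude > 0:
        r, c = np.ogrid[:s, :s]
        blob = np.exp(-(((r - cr) / rr) ** 2 + ((c - cc) / rc) ** 2))
        img += amplitude * blob

    if profile.invert_by_department.get(department, False):
        img = 1.0 - img

    if profile.token is not None and profile.token.intensity > 0:
        side = profile.token.side
        m = 1
        r0 = m if profile.token.corner.startswith("top") else s - m - side
        c0 = m if profile.token.corner.endswith("left") else s - m - side
        block = img[r0 : r0 + side, c0 : c0 + side]
        img[r0 : r0 + side, c0 : c0 + side] = np.maximum(block, profile.token.intensity)

    if profile.banner is not None:
        rows_slice = (
            slice(0, profile.banner.rows)
            if profile.banner.edge == "top"
            else slice(s - profile.banner.rows, s)
        )
        band = np.full((profile.banner.rows, s), profile.banner.intensity)
        dashes = rng.random(s) < 0.25  # text-like dark dashes
        band[:, dashes] = 0.35
        img[rows_slice, :] = band

    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Reports

_POSITIVE_TEMPLATES = {
    "pneumonia": [
        "airspace opacity most consistent with pneumonia",
        "findings suggestive of developing pneumonia",
        "patchy consolidation worrisome for pneumonia",
    ],
    "cardiomegaly": ["the cardiac silhouette is enlarged consistent with cardiomegaly",
                     "moderate cardiomegaly is present"],
    "emphysema": ["hyperinflated lungs with emphysema", "changes of emphysema are noted"],
    "effusion": ["there is a layering pleural effusion", "small right pleural effusion"],
    "hernia": ["a hiatal hernia is noted", "large hiatal hernia above the diaphragm"],
    "nodule": ["a pulmonary nodule is seen", "rounded nodule in the upper lobe"],
    "atelectasis": ["bibasilar atelectasis is present", "linear atelectasis at the base"],
    "edema": ["vascular congestion with interstitial edema", "mild pulmonary edema"],
    "consolidation": ["focal consolidation in the lower lobe",
                      "dense consolidation is identified"],
}

_NEGATION_TEMPLATES = [
    "no {term}",
    "no evidence of {term}",
    "without {term}",
    "prior {term} has resolved",
]

_NORMAL_SENTENCES = [
    "the lungs are clear",
    "heart size is normal",
    "no acute cardiopulmonary abnormality",
    "osseous structures are intact",
]


def generate_report(record: StudyRecord, rng: np.random.Generator) -> str:
    """Templated free-text report consistent with the record's labels.

    Every positive finding is asserted with one of its lexical variants
    (hernia-positive reports always contain the token "hernia"); a random
    subset of negative findings is explicitly negated; remaining sentences
    are normal boilerplate. A finding whose label is 0 never appears
    without a negation cue.
    """
    sentences = []
    for finding in FINDINGS:
        if record.labels[finding]:
            variants = _POSITIVE_TEMPLATES[finding]
            sentences.append(variants[int(rng.integers(len(variants)))])
        elif rng.random() < 0.35:
            template = _NEGATION_TEMPLATES[int(rng.integers(len(_NEGATION_TEMPLATES)))]
            sentences.append(template.format(term=finding))
    if not any(record.labels.values()):
        sentences.append(_NORMAL_SENTENCES[int(rng.integers(len(_NORMAL_SENTENCES)))])
    order = rng.permutation(len(sentences))
    return ". ".join(sentences[i].capitalize() for i in order) + "."


# ---------------------------------------------------------------------------
# Study-set generation


def _truncated_geometric(rng: np.random.Generator, mean: float, maximum: int) -> int:
    if mean <= 1.0:
        return 1
    return int(min(rng.geometric(1.0 / mean), maximum))


def _assign_exact_positives(
    site_id: str,
    patient_ids: np.ndarray,
    sexes: np.ndarray,
    prevalence: float,
    persistence: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact-count pneumonia assignment with within-patient clustering.

    The number of positive studies is exactly round(prevalence * n) per
    site, balanced so each sex's prevalence matches the site prevalence to
    within one study. Positives cluster within patients — after a
    patient's first positive study, each further study is positive with
    probability ``persistence`` — emulating disease episodes that span
    several studies (and making patient-level splitting matter).
    """
    n = len(sexes)
    n_pos = round(prevalence * n)
    labels = np.zeros(n, dtype=int)
    if n_pos == 0:
        return labels
    female_idx = np.nonzero(sexes == "F")[0]
    male_idx = np.nonzero(sexes == "M")[0]
    pos_f = round(prevalence * len(female_idx))
    pos_m = n_pos - pos_f
    for stratum, idx, need in [("F", female_idx, pos_f), ("M", male_idx, pos_m)]:
        if need < 0 or need > len(idx):
            raise ValueError(
                f"site {site_id!r}: prevalence {prevalence} unsatisfiable in sex "
                f"stratum {stratum} ({len(idx)} candidates, {need} positives needed)"
            )
        if not need:
            continue
        by_patient: dict[str, list[int]] = {}
        for i in idx:
            by_patient.setdefault(patient_ids[i], []).append(int(i))
        patients = sorted(by_patient)
        order = rng.permutation(len(patients))
        remaining = need
        for p in order:
            if remaining == 0:
                break
            studies = by_patient[patients[p]]
            cluster = 1 + int(rng.binomial(len(studies) - 1, persistence))
            take = min(cluster, remaining)
            chosen = rng.choice(studies, size=take, replace=False)
            labels[chosen] = 1
            remaining -= take
        if remaining:  # top up (only reachable at extreme prevalence)
            open_idx = [i for i in idx if labels[i] == 0]
            labels[rng.choice(open_idx, size=remaining, replace=False)] = 1
    return labels


def generate_study_set(
    config: GeneratorConfig, profiles: list[SiteProfile]
) -> list[StudyRecord]:
    """Generate the full multi-site study set.

    Per site, the number of pneumonia-positive studies is exactly
    round(prevalence * n_studies); all of a patient's studies share one
    site; images are rendered consistently with the assigned labels.
    """
    if not profiles:
        raise ValueError("need at least one site profile")
    root = np.random.SeedSequence(config.seed)
    site_seeds = root.spawn(len(profiles))
    records: list[StudyRecord] = []

    for profile, site_seq in zip(profiles, site_seeds):
        struct_seq, image_parent, report_seq = site_seq.spawn(3)
        rng = np.random.default_rng(struct_seq)
        report_rng = np.random.default_rng(report_seq)
        n_patients = config.n_patients(profile.site_id)
        departments = sorted(profile.department_mix)
        dept_p = np.array([profile.department_mix[d] for d in departments])

        site_records: list[StudyRecord] = []
        for i in range(n_patients):
            pid = f"{profile.site_id}-p{i:05d}"
            sex = "F" if rng.random() < profile.sex_female_fraction else "M"
            age = float(np.clip(
                rng.normal(profile.age_mean_sd[0], profile.age_mean_sd[1]), 18.0, 95.0
            ))
            n_studies = _truncated_geometric(
                rng, config.studies_per_patient_mean, config.max_studies_per_patient
            )
            for j in range(n_studies):
                department = departments[int(rng.choice(len(departments), p=dept_p))]
                view = "lateral" if rng.random() < config.lateral_fraction else "frontal"
                site_records.append(
                    StudyRecord(
                        patient_id=pid,
                        study_id=f"{pid}-s{j}",
                        site_id=profile.site_id,
                        department=department,
                        view=view,
                        sex=sex,
                        age=age,
                        labels={},
                    )
                )

        sexes = np.array([r.sex for r in site_records])
        pids = np.array([r.patient_id for r in site_records])
        pneumonia = _assign_exact_positives(
            profile.site_id, pids, sexes, profile.prevalence,
            config.disease_persistence, rng,
        )
        other = {
            f: (rng.random(len(site_records)) < rate).astype(int)
            for f, rate in DEFAULT_FINDING_RATES.items()
        }
        image_seeds = image_parent.spawn(len(site_records))
        for k, record in enumerate(site_records):
            record.labels = {f: int(other[f][k]) for f in FINDINGS if f != "pneumonia"}
            record.labels["pneumonia"] = int(pneumonia[k])
            record.labels = {f: record.labels[f] for f in FINDINGS}
            if config.render_images:
                record.image = render_image(
                    record.view,
                    record.department,
                    record.labels["pneumonia"],
                    profile,
                    np.random.default_rng(image_seeds[k]),
                    config,
                ).astype(np.float32)
            if config.make_reports:
                record.report = generate_report(record, report_rng)
        records.extend(site_records)
    return records


# ---------------------------------------------------------------------------
# I/O


def records_to_manifest(records: list[StudyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "study_id": r.study_id,
            "site": r.site_id,
            "department": r.department,
            "view": r.view,
            "sex": r.sex,
            "age": r.age,
        }
        row.update({f: r.labels[f] for f in FINDINGS})
        rows.append(row)
    return pd.DataFrame(rows)


def write_study_set(records: list[StudyRecord], outdir: str | Path, images: bool = True) -> None:
    """Write images (8-bit PNG), a CSV manifest, and a reports JSONL."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = records_to_manifest(records)
    if images:
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        paths = []
        for r in records:
            path = img_dir / f"{r.study_id}.png"
            arr = (np.clip(r.image, 0, 1) * 255).round().astype(np.uint8)
            Image.fromarray(arr, mode="L").save(path)
            paths.append(str(path.relative_to(outdir)))
        manifest["image_path"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "reports.jsonl", "w") as fh:
        for r in records:
            if r.report is not None:
                fh.write(json.dumps({"study_id": r.study_id, "text": r.report}) + "\n")
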