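"""Patient-level splitting and engineered-prevalence cohort sampling.

Splits are assigned at the patient (or accession-group) level so that no
patient's studies straddle train/tune/test — the leakage-prevention step
that matters when patients contribute several studies.

Engineered prevalence cohorts subsample two source sites to preset
per-site disease prevalences while holding the overall prevalence
constant, the instrument used to show that a classifier exploits a
site-prevalence shortcut: internal (pooled) test performance rises with
the engineered imbalance while external performance does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import StudyRecord

SPLITS = ("train", "tune", "test")


@dataclass
class SplitAssignment:
    """Mapping patient (group) id -> split name."""

    assignment: dict[str, str]

    def of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def members(self, split: str) -> set[str]:
        return {p for p, s in self.assignment.items() if s == split}

    def subset(self, records: list[StudyRecord], split: str, key=lambda r: r.patient_id):
        return [r for r in records if self.assignment[key(r)] == split]


def _largest_remainder_counts(n: int, fractions) -> list[int]:
    """Integer allocation of n among fractions; sizes within one of n*f."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    short = n - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # largest remainder first
    for i in range(short):
        counts[order[i]] += 1
    return counts


def split_by_patient(
    records: list[StudyRecord],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
    key=lambda r: r.patient_id,
    stratify: bool = False,
) -> SplitAssignment:
    """Assign each patient (grouping key) to fixed train/tune/test splits.

    ``key`` defaults to patient id; pass an accession-style key for data
    without stable patient identifiers. With ``stratify`` the allocation is
    performed within (site, patient-level pneumonia) strata, so every split
    receives its proportional share of positive patients from every site —
    useful at small scale, where an unstratified draw can leave a rare-
    disease site with no evaluable positives in the test split (each
    stratum's fractions are then within one patient of the targets, rather
    than the global counts being exact).
    """
    if not records:
        raise ValueError("no records to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    if stratify:
        info: dict[str, tuple] = {}
        for r in records:
            k = key(r)
            site, pos = info.get(k, (r.site_id, 0))
            info[k] = (site, max(pos, r.labels["pneumonia"]))
        strata: dict[tuple, list[str]] = {}
        for k, s in info.items():
            strata.setdefault(s, []).append(k)
        groups = [sorted(strata[s]) for s in sorted(strata)]
    else:
        groups = [sorted({key(r) for r in records})]
    for patients in groups:
        order = rng.permutation(len(patients))
        counts = _largest_remainder_counts(len(patients), fractions)
        start = 0
        for split, count in zip(SPLITS, counts):
            for idx in order[start : start + count]:
                assignment[patients[idx]] = split
            start += count
    return SplitAssignment(assignment=assignment)


# ---------------------------------------------------------------------------
# Engineered prevalence cohorts


@dataclass
class EngineeredCohortSpec:
    """Two-site cohort design with preset per-site disease prevalence."""

    name: str
    site_a: str
    prevalence_a: float
    site_b: str
    prevalence_b: float
    patients_per_site: int = 10_000

    @property
    def overall_prevalence(self) -> float:
        return (self.prevalence_a + self.prevalence_b) / 2.0

    @property
    def relative_risk(self) -> float:
        return self.prevalence_a / self.prevalence_b


def standard_specs(
    site_a: str = "site_a",
    site_b: str = "site_b",
    patients_per_site: int = 10_000,
) -> list[EngineeredCohortSpec]:
    """The five standard designs, ordered from A-severe to B-severe.

    Site-A prevalence decreases (9.9, 9, 5, 1, 0.1 percent) while site-B
    increases symmetrically, so every design has the same 5% overall
    prevalence.
    """
    designs = [
        ("a_severe", 0.099, 0.001),
        ("a_mild", 0.09, 0.01),
        ("balanced", 0.05, 0.05),
        ("b_mild", 0.01, 0.09),
        ("b_severe", 0.001, 0.099),
    ]
    return [
        EngineeredCohortSpec(
            name=name,
            site_a=site_a,
            prevalence_a=pa,
            site_b=site_b,
            prevalence_b=pb,
            patients_per_site=patients_per_site,
        )
        for name, pa, pb in designs
    ]


def patient_table(records: list[StudyRecord]) -> dict[str, dict]:
    """Collapse study records to patients: site, sex, any-positive pneumonia."""
    table: dict[str, dict] = {}
    for r in records:
        entry = table.setdefault(
            r.patient_id, {"site": r.site_id, "sex": r.sex, "pneumonia": 0}
        )
        if r.site_id != entry["site"]:
            raise ValueError(f"patient {r.patient_id} appears at multiple sites")
        entry["pneumonia"] = max(entry["pneumonia"], r.labels["pneumonia"])
    return table


def _allocate_capped(need: int, capacities: list[int]) -> list[int]:
    """Proportional largest-remainder allocation of need, capped per bin."""
    total = sum(capacities)
    raw = [need * c / total for c in capacities]
    alloc = [min(int(np.floor(x)), c) for x, c in zip(raw, capacities)]
    order = sorted(
        range(len(capacities)), key=lambda i: alloc[i] - raw[i]
    )  # largest remainder first
    short = need - sum(alloc)
    while short > 0:
        progressed = False
        for i in order:
            if short == 0:
                break
            if alloc[i] < capacities[i]:
                alloc[i] += 1
                short -= 1
                progressed = True
        if not progressed:
            break
    return alloc


def engineer_prevalence_cohort(
    records: list[StudyRecord],
    spec: EngineeredCohortSpec,
    seed: int = 0,
    balance_sex_within_site: bool = True,
    splits: SplitAssignment | None = None,
) -> tuple[list[str], list[StudyRecord]]:
    """Sample a two-site cohort with exact per-site positive counts.

    Per site, positives = round(prevalence * patients_per_site) exactly
    (half-to-even rounding); within a site, positives and negatives are
    split evenly between the sexes so that male and female prevalence agree
    to within one patient. Sampling is without replacement and fully
    deterministic given the seed. Patients keep whatever split membership
    they already have — the function subsamples, it does not re-split; when
    a ``splits`` assignment is supplied, each stratum's quota is spread
    across train/tune/test in proportion to the source pool, so the cohort's
    splits mirror the pool's and every split retains its share of positives.

    Returns (sampled patient ids, their study records).
    """
    patients = patient_table(records)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for site, prevalence in [(spec.site_a, spec.prevalence_a), (spec.site_b, spec.prevalence_b)]:
        n = spec.patients_per_site
        n_pos = round(prevalence * n)
        n_neg = n - n_pos
        if balance_sex_within_site:
            quotas = []
            for label, total in [(1, n_pos), (0, n_neg)]:
                n_f = round(total / 2)
                quotas += [(label, "F", n_f), (label, "M", total - n_f)]
        else:
            quotas = [(1, None, n_pos), (0, None, n_neg)]
        for label, sex, need in quotas:
            pool = sorted(
                p
                for p, e in patients.items()
                if e["site"] == site
                and e["pneumonia"] == label
                and (sex is None or e["sex"] == sex)
            )
            if need > len(pool):
                stratum = f"site={site}, pneumonia={label}" + (f", sex={sex}" if sex else "")
                raise ValueError(
                    f"cohort {spec.name!r} infeasible: stratum ({stratum}) has "
                    f"{len(pool)} candidates, {need} required"
                )
            if not need:
                continue
            if splits is None:
                chosen.extend(rng.choice(pool, size=need, replace=False))
            else:
                by_split = {s: [p for p in pool if splits.of(p) == s] for s in SPLITS}
                allocation = _allocate_capped(need, [len(by_split[s]) for s in SPLITS])
                for s, take in zip(SPLITS, allocation):
                    if take:
                        chosen.extend(rng.choice(by_split[s], size=take, replace=False))
    chosen_set = set(chosen)
    cohort_records = [r for r in records if r.patient_id in chosen_set]
    return chosen, cohort_records
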