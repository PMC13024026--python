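"""Cohort manifests: scan records, quality filtering, leakage-safe splits.

A manifest lists one row per scan.  Roles fall into four *families* that
must not share subjects, since longitudinal and test-retest scans used for
evaluation would otherwise leak into model development:

* development: ``train``, ``val``, ``test`` (and the pre-split ``unsplit``)
* ``unseen`` external evaluation
* ``longitudinal_baseline`` / ``longitudinal_followup``
* ``retest_1`` / ``retest_2``
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

ROLES = ("train", "val", "test", "unseen", "longitudinal_baseline",
         "longitudinal_followup", "retest_1", "retest_2", "unsplit")
DEV_ROLES = ("train", "val", "test", "unsplit")

ROLE_FAMILY = {r: "development" for r in DEV_ROLES}
ROLE_FAMILY.update({"unseen": "unseen",
                    "longitudinal_baseline": "longitudinal",
                    "longitudinal_followup": "longitudinal",
                    "retest_1": "retest", "retest_2": "retest"})

MANIFEST_COLUMNS = ["scan_id", "subject_id", "age", "sex", "site", "role",
                    "iqr_score", "path"]


@dataclass(frozen=True)
class ScanRecord:
    scan_id: str
    subject_id: str
    age: float
    sex: str = "unknown"
    site: str = "site0"
    role: str = "unsplit"
    iqr_score: float | None = None
    path: str = ""

    def __post_init__(self):
        if not np.isfinite(self.age) or not (0.0 <= self.age <= 130.0):
            raise ValueError(f"age {self.age} for scan {self.scan_id} outside [0, 130]")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for scan {self.scan_id}")
        if self.sex not in ("M", "F", "unknown"):
            raise ValueError(f"unknown sex {self.sex!r} for scan {self.scan_id}")


@dataclass
class CohortManifest:
    records: list[ScanRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subjects(self, roles=None) -> list[str]:
        seen, out = set(), []
        for r in self.records:
            if roles is not None and r.role not in roles:
                continue
            if r.subject_id not in seen:
                seen.add(r.subject_id)
                out.append(r.subject_id)
        return out

    def select(self, roles) -> "CohortManifest":
        roles = {roles} if isinstance(roles, str) else set(roles)
        return CohortManifest([r for r in self.records if r.role in roles],
                              self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "scan_id": r.scan_id, "subject_id": r.subject_id, "age": r.age,
            "sex": r.sex, "site": r.site, "role": r.role,
            "iqr_score": r.iqr_score, "path": r.path,
        } for r in self.records], columns=MANIFEST_COLUMNS)

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance="") -> "CohortManifest":
        recs = []
        for row in df.itertuples(index=False):
            iqr = getattr(row, "iqr_score", None)
            iqr = None if iqr is None or (isinstance(iqr, float) and np.isnan(iqr)) else float(iqr)
            path = getattr(row, "path", "")
            path = "" if path is None or (isinstance(path, float) and np.isnan(path)) else str(path)
            recs.append(ScanRecord(
                scan_id=str(row.scan_id), subject_id=str(row.subject_id),
                age=float(row.age), sex=str(getattr(row, "sex", "unknown")),
                site=str(getattr(row, "site", "site0")),
                role=str(getattr(row, "role", "unsplit")),
                iqr_score=iqr, path=path))
        return cls(recs, provenance)

    @classmethod
    def from_csv(cls, path) -> "CohortManifest":
        return cls.from_frame(pd.read_csv(path), provenance=str(path))


def filter_by_quality(manifest: CohortManifest, threshold: float = 75.0):
    """Drop scans whose image-quality rating falls below `threshold`.

    The boundary is kept (strictly-below exclusion).  Records without a
    score are retained and returned in the `unscored` list for review.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    kept, unscored = [], []
    for r in manifest.records:
        if r.iqr_score is None:
            kept.append(r)
            unscored.append(r.scan_id)
        elif r.iqr_score >= threshold:
            kept.append(r)
    return CohortManifest(kept, manifest.provenance), unscored


def split_cohort(manifest: CohortManifest, fractions=(0.70, 0.15, 0.15),
                 seed: int = 0, stratify_by_age: bool = False,
                 n_strata: int = 8) -> CohortManifest:
    """Assign `unsplit` development records to train/val/test at subject level.

    Every scan of a subject lands in the same split.  With
    ``stratify_by_age`` the subject pool is quantile-binned on mean age and
    each bin is divided independently, balancing the age distribution.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    pool = [r for r in manifest.records if r.role == "unsplit"]
    subjects = sorted({r.subject_id for r in pool})
    if len(subjects) < 3:
        raise ValueError(f"need at least 3 subjects to split, got {len(subjects)}")
    rng = np.random.default_rng(seed)

    def partition(subs):
        subs = np.asarray(subs)
        perm = rng.permutation(len(subs))
        n_train = int(round(fractions[0] * len(subs)))
        n_val = int(round(fractions[1] * len(subs)))
        n_val = min(n_val, len(subs) - n_train)
        out = {}
        for i, s in enumerate(subs[perm]):
            out[s] = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        return out

    if stratify_by_age:
        mean_age = {}
        for r in pool:
            mean_age.setdefault(r.subject_id, []).append(r.age)
        ages = np.array([np.mean(mean_age[s]) for s in subjects])
        edges = np.quantile(ages, np.linspace(0, 1, n_strata + 1)[1:-1])
        bins = np.searchsorted(edges, ages)
        assign = {}
        for b in np.unique(bins):
            assign.update(partition([s for s, bb in zip(subjects, bins) if bb == b]))
    else:
        assign = partition(subjects)

    new = [replace(r, role=assign[r.subject_id]) if r.role == "unsplit" else r
           for r in manifest.records]
    return CohortManifest(new, manifest.provenance)


def validate_manifest(manifest: CohortManifest) -> list[str]:
    """Return human-readable invariant violations; empty list iff valid."""
    violations = []
    seen_ids: dict[str, int] = {}
    for i, r in enumerate(manifest.records):
        if r.scan_id in seen_ids:
            violations.append(
                f"duplicate scan_id {r.scan_id!r} (records {seen_ids[r.scan_id]} and {i})")
        else:
            seen_ids[r.scan_id] = i
        if not (0.0 <= r.age <= 130.0):
            violations.append(f"age {r.age} out of range for scan {r.scan_id!r}")
    fam: dict[str, set] = {}
    for r in manifest.records:
        fam.setdefault(r.subject_id, set()).add(ROLE_FAMILY[r.role])
    for subj, fams in sorted(fam.items()):
        if len(fams) > 1:
            violations.append(
                f"subject {subj!r} appears in multiple role families: {sorted(fams)}")
    return violations
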