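"""Affinity index parsing, train/validation/test splitting, pose augmentation.

The index format follows the PDBbind convention: whitespace-delimited lines
``code  resolution  year  -logKd/Ki  ...`` with ``#`` comment lines. Labels
are −log10(Kd/Ki) (pKd/pKi). Held-out test sets (e.g. core-set id lists) are
removed from the pool before a seeded uniform draw of the validation set
(default 10% of the remainder, the 9:1 convention), optionally restricted to
refined-tier complexes. Docking-pose augmentation attaches, per training or
validation complex, at most ``max_poses`` poses with RMSD ≤ ``rmsd_max`` Å to
the crystal pose, preferring the best (lowest-energy) docking scores; test
complexes never gain poses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_VAL_FRACTION = 0.1
DEFAULT_RMSD_MAX = 3.0
DEFAULT_MAX_POSES = 3

QUALITY_TIERS = ("refined", "general-only")


class IndexParseError(ValueError):
    """Malformed affinity index line."""


@dataclass
class ComplexRecord:
    id: str
    label: float  # -log10(Kd/Ki)
    quality_tier: str = "refined"
    protein_path: str | None = None
    ligand_path: str | None = None

    def __post_init__(self):
        if self.quality_tier not in QUALITY_TIERS:
            raise ValueError(f"unknown quality tier {self.quality_tier!r}")
        if not np.isfinite(self.label):
            raise ValueError(f"complex {self.id}: non-finite label {self.label}")


@dataclass
class PoseRecord:
    parent_id: str
    pose_path: str
    docking_score: float
    rmsd: float  # Å vs the crystal pose

    def __post_init__(self):
        if self.rmsd < 0:
            raise ValueError(f"pose for {self.parent_id}: negative RMSD")


@dataclass
class SplitManifest:
    train: list[ComplexRecord]
    validation: list[ComplexRecord]
    test_sets: dict[str, list[ComplexRecord]]
    seed: int
    poses: dict[str, list[PoseRecord]] = field(default_factory=dict)
    notes: str = ""

    def split_ids(self) -> dict[str, set[str]]:
        out = {"train": {r.id for r in self.train}, "validation": {r.id for r in self.validation}}
        for name, recs in self.test_sets.items():
            out[name] = {r.id for r in recs}
        return out

    def to_json(self, path: str) -> None:
        def enc(records):
            return [asdict(r) for r in records]

        payload = {
            "seed": self.seed,
            "notes": self.notes,
            "train": enc(self.train),
            "validation": enc(self.validation),
            "test_sets": {k: enc(v) for k, v in self.test_sets.items()},
            "poses": {k: enc(v) for k, v in self.poses.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SplitManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            train=[ComplexRecord(**r) for r in d["train"]],
            validation=[ComplexRecord(**r) for r in d["validation"]],
            test_sets={k: [ComplexRecord(**r) for r in v] for k, v in d["test_sets"].items()},
            seed=d["seed"],
            poses={k: [PoseRecord(**r) for r in v] for k, v in d.get("poses", {}).items()},
            notes=d.get("notes", ""),
        )


# ---------------------------------------------------------------------------
# Index parsing


def parse_index(path: str, quality_tier: str = "refined") -> list[ComplexRecord]:
    """One ComplexRecord per data line; '#' lines are comments; the label is
    the fourth column (−logKd/Ki in the PDBbind convention)."""
    records: list[ComplexRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise IndexParseError(f"{path}:{lineno}: expected ≥4 columns, got {len(fields)}")
            code = fields[0]
            try:
                label = float(fields[3])
            except ValueError:
                raise IndexParseError(f"{path}:{lineno}: unparseable label {fields[3]!r}") from None
            if code in seen:
                raise IndexParseError(f"{path}:{lineno}: duplicate complex code {code!r}")
            seen.add(code)
            records.append(ComplexRecord(id=code, label=label, quality_tier=quality_tier))
    return records


def read_id_list(path: str) -> set[str]:
    """Id-list file: one complex code per line, '#' comments allowed."""
    with open(path) as fh:
        return {
            line.strip() for line in fh if line.strip() and not line.lstrip().startswith("#")
        }


# ---------------------------------------------------------------------------
# Splitting


def make_splits(
    records: list[ComplexRecord],
    exclude_test_ids: dict[str, set[str]] | None = None,
    val_fraction: float = DEFAULT_VAL_FRACTION,
    val_pool: str | None = None,
    seed: int = 0,
) -> SplitManifest:
    """Remove each named test-id set from the pool, then draw the validation
    set uniformly at random (seeded) as ``val_fraction`` of what remains,
    restricted to ``val_pool``-tier records when given; the rest is train."""
    exclude_test_ids = exclude_test_ids or {}
    by_id = {r.id: r for r in records}
    test_sets: dict[str, list[ComplexRecord]] = {}
    excluded: set[str] = set()
    for name, ids in exclude_test_ids.items():
        unknown = ids - set(by_id)
        if unknown:
            logger.warning("test list %s: %d ids not in the index", name, len(unknown))
        test_sets[name] = [by_id[i] for i in sorted(ids & set(by_id))]
        excluded |= ids

    pool = [r for r in records if r.id not in excluded]
    if not pool:
        raise ValueError("no complexes remain after removing test sets")

    n_val = int(round(val_fraction * len(pool)))
    eligible = [r for r in pool if val_pool is None or r.quality_tier == val_pool]
    if n_val > len(eligible):
        raise ValueError(
            f"validation needs {n_val} complexes but only {len(eligible)} are {val_pool}-tier"
        )
    rng = np.random.default_rng(seed)
    val_idx = set(rng.choice(len(eligible), size=n_val, replace=False).tolist())
    val_ids = {eligible[i].id for i in val_idx}
    validation = [r for r in pool if r.id in val_ids]
    train = [r for r in pool if r.id not in val_ids]
    return SplitManifest(train=train, validation=validation, test_sets=test_sets, seed=seed)


# ---------------------------------------------------------------------------
# Docking-pose augmentation


def read_pose_table(path: str) -> list[PoseRecord]:
    """CSV with columns parent_id, pose_path, docking_score, rmsd."""
    df = pd.read_csv(path)
    required = {"parent_id", "pose_path", "docking_score", "rmsd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pose table missing columns {sorted(missing)}")
    return [
        PoseRecord(
            parent_id=str(r.parent_id),
            pose_path=str(r.pose_path),
            docking_score=float(r.docking_score),
            rmsd=float(r.rmsd),
        )
        for r in df.itertuples()
    ]


def augment_with_poses(
    manifest: SplitManifest,
    poses: list[PoseRecord],
    rmsd_max: float = DEFAULT_RMSD_MAX,
    max_poses: int = DEFAULT_MAX_POSES,
) -> SplitManifest:
    """Attach docking poses to their parent train/validation complexes.

    Poses with RMSD > ``rmsd_max`` are discarded; among the survivors at most
    ``max_poses`` with the best (lowest) docking score are kept per complex.
    Poses referencing test complexes are rejected with a warning; the split
    membership itself never changes.
    """
    split_ids = manifest.split_ids()
    trainable = split_ids["train"] | split_ids["validation"]
    test_ids = set().union(*(v for k, v in split_ids.items() if k not in ("train", "validation")), set())

    by_parent: dict[str, list[PoseRecord]] = {}
    for pose in poses:
        if pose.parent_id in test_ids:
            logger.warning("pose for test complex %s rejected", pose.parent_id)
            continue
        if pose.parent_id not in trainable:
            logger.warning("pose for unknown complex %s rejected", pose.parent_id)
            continue
        if pose.rmsd > rmsd_max:
            continue
        by_parent.setdefault(pose.parent_id, []).append(pose)

    kept = {
        pid: sorted(plist, key=lambda p: p.docking_score)[:max_poses]
        for pid, plist in by_parent.items()
    }
    return SplitManifest(
        train=manifest.train,
        validation=manifest.validation,
        test_sets=manifest.test_sets,
        seed=manifest.seed,
        poses=kept,
        notes=manifest.notes,
    )
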