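"""Seeded synthetic studies with planted coactivity structure.

The generator emulates the kind of dataset the analysis expects: a small
number of behavioral conditions, 7-9 subjects each, and ~13 brain regions
whose c-Fos densities (cells/mm^3) carry a planted block-correlation
structure. Each condition draws from a multivariate normal whose
correlation matrix follows a planted module partition: pairs sharing a
module correlate at ``rho_within``, pairs in different modules at the
``rho_between`` value declared for that module pair (default 0, and
possibly negative, as anticorrelated blocks are a hallmark of
agonistic-encounter networks).

Densities are generated on the raw scale and clipped at zero, so the
planted Pearson correlations are the targets downstream stages should
recover; choosing means at least four standard deviations above zero makes
clipping negligible.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ModulePartition
from .coactivity import DensityTable
from .regions import SDMN_REGIONS, RegionSet

#: below this, a (negative) minimum eigenvalue counts as numerical noise and
#: the matrix is nudged PSD by adding 1e-10 to the diagonal; anything worse
#: is a genuine specification error and is rejected.
_PSD_NUDGE_FLOOR = -1e-10


@dataclass(frozen=True)
class ConditionSpec:
    """Planted data-generating process for one condition."""

    condition_name: str
    n_subjects: int
    region_means: dict[str, float]
    region_sds: dict[str, float]
    planted_partition: dict[str, int]
    rho_within: float = 0.0
    rho_between: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        regions = list(self.region_means)
        for name, mapping in (
            ("region_sds", self.region_sds),
            ("planted_partition", self.planted_partition),
        ):
            if set(mapping) != set(regions):
                raise ValueError(f"{name} must cover exactly the regions in region_means")
        if any(m <= 0 for m in self.region_means.values()):
            raise ValueError("region means must be > 0 (densities)")
        if any(s <= 0 for s in self.region_sds.values()):
            raise ValueError("region sds must be > 0")
        if not -1.0 <= self.rho_within <= 1.0:
            raise ValueError("rho_within must lie in [-1, 1]")
        for pair, rho in self.rho_between.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"rho_between[{pair}] must lie in [-1, 1]")
        # validate PSD once, at construction
        self.correlation_target()

    @property
    def region_set(self) -> RegionSet:
        return RegionSet(self.region_means)

    def correlation_target(self) -> np.ndarray:
        """The planted interregional correlation matrix (validated PSD)."""
        regions = list(self.region_means)
        p = len(regions)
        mods = [self.planted_partition[r] for r in regions]
        C = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                if mods[i] == mods[j]:
                    rho = self.rho_within
                else:
                    key = tuple(sorted((mods[i], mods[j])))
                    rho = self.rho_between.get(key, 0.0)
                C[i, j] = C[j, i] = rho
        w = np.linalg.eigvalsh(C)
        if w[0] < _PSD_NUDGE_FLOOR:
            raise ValueError(
                "planted correlation matrix is not positive semi-definite "
                f"(minimum eigenvalue {w[0]:.3e})"
            )
        if w[0] < 0:
            C = C + 1e-10 * np.eye(p)
        return C


@dataclass(frozen=True)
class StudyDataset:
    """A full multi-condition study plus its ground truth."""

    conditions: dict[str, DensityTable]
    region_set: RegionSet
    truth: dict[str, ModulePartition]
    seed: int

    def to_long(self) -> pd.DataFrame:
        return pd.concat(
            [t.to_long() for t in self.conditions.values()], ignore_index=True
        )

    def write_long(self, path) -> Path:
        """Canonical long-format input: subject_id, condition, region, density."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_long().to_csv(path, index=False)
        return path

    def write_truth(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        rows = [
            {"region": r, "module_id": m, "condition": cond}
            for cond, part in self.truth.items()
            for r, m in part.assignment.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        return path


def _substream(master_seed: int, condition_name: str) -> np.random.Generator:
    """Per-condition RNG derived from (master seed, stable hash of name).

    The name is hashed with SHA-256 so adding or reordering conditions does
    not perturb the draws of any other condition.
    """
    digest = hashlib.sha256(condition_name.encode("utf-8")).digest()
    name_key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), name_key]))


def generate_condition(spec: ConditionSpec, seed: int) -> DensityTable:
    """Draw one condition's subjects x regions density table.

    Multivariate normal with the planted correlation structure, scaled to
    ``region_sds`` and shifted to ``region_means``; draws below zero are
    clipped to zero (densities cannot be negative) and counted.
    """
    regions = list(spec.region_means)
    C = spec.correlation_target()
    # eigenfactor rather than Cholesky: tolerates exactly singular targets
    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0.0, None))

    rng = _substream(seed, spec.condition_name)
    z = rng.standard_normal((spec.n_subjects, len(regions)))
    x = z @ L.T
    sds = np.array([spec.region_sds[r] for r in regions])
    means = np.array([spec.region_means[r] for r in regions])
    x = x * sds + means

    n_clipped = int((x < 0).sum())
    if n_clipped:
        warnings.warn(
            f"{n_clipped} density value(s) below 0 clipped in condition "
            f"{spec.condition_name!r}; consider means >= 4 sd"
        )
        x = np.clip(x, 0.0, None)

    subjects = [f"{spec.condition_name}_s{i + 1:02d}" for i in range(spec.n_subjects)]
    return DensityTable(
        condition=spec.condition_name,
        region_set=spec.region_set,
        data=pd.DataFrame(x, index=subjects, columns=regions),
        n_clipped=n_clipped,
    )


def generate_study(specs: list[ConditionSpec], seed: int) -> StudyDataset:
    """One density table per condition, each from its own seeded substream."""
    if not specs:
        raise ValueError("at least one condition spec is required")
    names = [s.condition_name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate condition names: {sorted(set(n for n in names if names.count(n) > 1))}")
    region_sets = {s.region_set.names for s in specs}
    if len(region_sets) != 1:
        raise ValueError("all condition specs must share one region set")

    conditions = {s.condition_name: generate_condition(s, seed) for s in specs}
    truth = {
        s.condition_name: ModulePartition(dict(s.planted_partition)) for s in specs
    }
    return StudyDataset(
        conditions=conditions,
        region_set=specs[0].region_set,
        truth=truth,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Canned study emulating the vole cohabitation experiment
# ---------------------------------------------------------------------------

#: Baseline c-Fos densities (cells/mm^3), one per SDMN region. Values are in
#: the low-thousands range typical of immediate-early-gene counts in small
#: rodent nuclei; standard deviations are mean/6 so that negative draws are
#: vanishingly rare.
_BASELINE_MEANS = {
    "AH": 2400.0,
    "BLA": 3100.0,
    "BNST": 2800.0,
    "HIP": 1900.0,
    "LS": 2600.0,
    "MeA": 2900.0,
    "mPOA": 3300.0,
    "NAcc": 3500.0,
    "PAG": 2100.0,
    "CP": 2700.0,
    "VMH": 2300.0,
    "VP": 2000.0,
    "VTA": 1700.0,
}

#: Which regions are elevated in which social condition. Eight of the
#: thirteen regions respond to at least one social stimulus: VMH in every
#: social encounter; mPOA, BNST, LS and VP with the partner and the same-sex
#: stranger; AH, MeA and VTA with the same-sex stranger only.
_ELEVATED = {
    "partner": ("VMH", "mPOA", "BNST", "LS", "VP"),
    "opposite_sex_stranger": ("VMH",),
    "same_sex_stranger": ("VMH", "mPOA", "BNST", "LS", "VP", "AH", "MeA", "VTA"),
}

_ELEVATION_FACTOR = 1.8  # fold-change of an elevated region over baseline


def default_condition_specs(
    n_subjects: dict[str, int] | None = None,
) -> list[ConditionSpec]:
    """The four canned condition specs (control / partner / two strangers).

    ``n_subjects`` overrides the default per-condition counts 7/9/9/9,
    which is useful for large-n recovery checks.
    """
    counts = {
        "control": 7,
        "partner": 9,
        "opposite_sex_stranger": 9,
        "same_sex_stranger": 9,
    }
    if n_subjects:
        counts.update(n_subjects)

    partitions: dict[str, dict[str, int]] = {
        # resting state: broad integration, three coupled blocks
        "control": {
            "AH": 1, "LS": 1, "mPOA": 1, "VP": 1, "BNST": 1,
            "BLA": 2, "CP": 2, "NAcc": 2, "HIP": 2,
            "MeA": 3, "VMH": 3, "PAG": 3, "VTA": 3,
        },
        # one large positively coupled social module, smaller reward block,
        # one isolate
        "partner": {
            "AH": 1, "LS": 1, "mPOA": 1, "VP": 1, "BNST": 1, "MeA": 1,
            "VMH": 1, "VTA": 1,
            "BLA": 2, "CP": 2, "NAcc": 2,
            "HIP": 3,
            "PAG": 4,
        },
        # fragmented: two anticorrelated blocks plus isolates
        "opposite_sex_stranger": {
            "AH": 1, "VTA": 1, "BNST": 1, "NAcc": 1,
            "mPOA": 2, "VMH": 2, "MeA": 2,
            "LS": 3, "VP": 4, "BLA": 5, "CP": 6, "HIP": 7, "PAG": 8,
        },
        # aggression block anticorrelated with the affiliative block
        "same_sex_stranger": {
            "AH": 1, "MeA": 1, "VTA": 1, "BNST": 1,
            "mPOA": 2, "LS": 2, "VP": 2, "VMH": 2,
            "BLA": 3, "CP": 3, "NAcc": 3, "HIP": 3,
            "PAG": 4,
        },
    }
    rho_between: dict[str, dict[tuple[int, int], float]] = {
        "control": {(1, 2): 0.3, (1, 3): 0.3, (2, 3): 0.3},
        "partner": {},
        "opposite_sex_stranger": {(1, 2): -0.5},
        "same_sex_stranger": {(1, 2): -0.55},
    }
    rho_within = {
        "control": 0.8,
        "partner": 0.75,
        "opposite_sex_stranger": 0.8,
        "same_sex_stranger": 0.8,
    }

    specs = []
    for cond in counts:
        means = dict(_BASELINE_MEANS)
        for region in _ELEVATED.get(cond, ()):
            means[region] = _BASELINE_MEANS[region] * _ELEVATION_FACTOR
        sds = {r: m / 6.0 for r, m in means.items()}
        specs.append(
            ConditionSpec(
                condition_name=cond,
                n_subjects=counts[cond],
                region_means=means,
                region_sds=sds,
                planted_partition=partitions[cond],
                rho_within=rho_within[cond],
                rho_between=rho_between[cond],
            )
        )
    return specs


def default_paper_study(seed: int) -> StudyDataset:
    """Canned 4-condition study over the 13 SDMN regions (counts 7/9/9/9)."""
    return generate_study(default_condition_specs(), seed)
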