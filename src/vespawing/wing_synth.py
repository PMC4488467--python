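"""Synthetic colony generator: pedigrees, genotypes, wings, replicates.

Emulates the study conditions the analysis assumes: colonies of haplodiploid
workers fathered by a handful of haploid males, genotyped at polymorphic
microsatellite loci, with 19-landmark right forewings whose log centroid
size and tangent-space shape carry colony, patriline, allometric and
individual effects, observed through two nested measurement-error layers
(wing mounting, then landmark digitization).

All shape effects are built directly in the 34-dimensional tangent space of
a fixed template wing, through an orthonormal basis of the complement of the
similarity transformations (translations, scaling, rotation). A tangent
vector of norm ``m`` therefore corresponds, to first order, to a Procrustes
distance ``m`` from the template -- which makes the generator's magnitudes
directly comparable to the distance statistics the pipeline estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import null_space

from .config import SimulationConfig
from .pedigree import MISSING, MultilocusGenotype
from .superimpose import LandmarkConfiguration

__all__ = [
    "TEMPLATE_WING",
    "ColonyTruth",
    "WingRecord",
    "WingDataset",
    "make_template_wing",
    "template_tangent_basis",
    "sample_pedigree",
    "sample_wings",
    "replicate_measurements",
    "simulate_study",
    "StudyData",
]

# Fixed 19-landmark template in arbitrary wing units: an elongate
# forewing-like configuration (length ~ 13.5, depth ~ 3.7) with landmarks at
# vein intersections along the costal margin (2-7), wing tip (8), and the
# median/anal vein network (9-19). Irregular by design so the configuration
# is generic (no symmetry, full tangent rank).
TEMPLATE_WING = np.array(
    [
        [0.00, 2.20],
        [1.60, 3.10],
        [3.40, 3.55],
        [5.90, 3.90],
        [7.80, 4.05],
        [9.60, 3.75],
        [11.60, 3.00],
        [13.40, 1.90],
        [11.90, 1.05],
        [10.10, 1.50],
        [8.45, 1.95],
        [7.00, 2.60],
        [6.30, 1.30],
        [5.10, 2.15],
        [4.20, 0.85],
        [2.90, 1.65],
        [1.90, 0.55],
        [0.90, 1.15],
        [6.95, 0.35],
    ]
)
N_LANDMARKS = TEMPLATE_WING.shape[0]


def make_template_wing() -> LandmarkConfiguration:
    """The fixed template wing; identical (copied) on every call."""
    return LandmarkConfiguration(TEMPLATE_WING.copy(), specimen_id="template")


@lru_cache(maxsize=1)
def _template_unit_and_basis() -> tuple[np.ndarray, np.ndarray]:
    x = TEMPLATE_WING - TEMPLATE_WING.mean(axis=0)
    x = x / np.sqrt((x**2).sum())
    t = x.ravel()
    k = N_LANDMARKS
    u_tx = np.tile([1.0, 0.0], k) / np.sqrt(k)
    u_ty = np.tile([0.0, 1.0], k) / np.sqrt(k)
    u_scale = t
    rot = np.column_stack([-x[:, 1], x[:, 0]]).ravel()
    u_rot = rot / np.linalg.norm(rot)
    similarity = np.stack([u_tx, u_ty, u_scale, u_rot])
    basis = null_space(similarity)  # (2k, 2k - 4), orthonormal
    basis.setflags(write=False)
    x.setflags(write=False)
    return x, basis


def template_tangent_basis() -> np.ndarray:
    """Orthonormal ``(2k, 2k-4)`` basis of the template's shape-tangent space."""
    return _template_unit_and_basis()[1]


@dataclass
class ColonyTruth:
    """Ground truth for one simulated colony (for recovery tests)."""

    colony_id: str
    queen_genotype: MultilocusGenotype
    father_haplotypes: list[dict[str, int]]
    worker_patriline_labels: dict[str, int]
    allele_frequencies: dict[str, np.ndarray]
    true_patriline_shape_effects: np.ndarray | None = None
    true_colony_shape_effect: np.ndarray | None = None
    true_allometry_direction: np.ndarray | None = None
    true_size_effects: dict[str, object] = field(default_factory=dict)

    @property
    def n_patrilines(self) -> int:
        return len(self.father_haplotypes)


@dataclass
class WingRecord:
    """One worker's wing: truth (tangent shape, log size) plus the observed
    (single mounting, single digitization) landmark configuration."""

    specimen_id: str
    colony_id: str
    patriline_true: int
    logcs_true: float
    tangent_true: np.ndarray
    config: LandmarkConfiguration
    damaged: bool


@dataclass
class WingDataset:
    records: list[WingRecord]

    def measured(self) -> list[WingRecord]:
        return [r for r in self.records if not r.damaged]

    def __len__(self) -> int:
        return len(self.records)


def _unit_vector(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def _identifiable(
    fathers: list[dict[str, int]], queen_alleles: dict[str, set[int]]
) -> bool:
    """Pairwise: some locus where the fathers differ and at least one of the
    two paternal alleles is absent from the queen (so daughters reveal it)."""
    for i in range(len(fathers)):
        for j in range(i + 1, len(fathers)):
            ok = False
            for locus, qa in queen_alleles.items():
                a, b = fathers[i][locus], fathers[j][locus]
                if a != b and (a not in qa or b not in qa):
                    ok = True
                    break
            if not ok:
                return False
    return True


def sample_pedigree(
    config: SimulationConfig, colony_index: int, seed: int
) -> tuple[ColonyTruth, list[MultilocusGenotype]]:
    """Draw one colony's queen, fathers and worker genotypes.

    Per-locus allele frequencies come from a symmetric Dirichlet with the
    configured concentration; the queen is diploid, fathers haploid; each
    worker receives one uniformly chosen maternal allele plus the father's
    allele at every locus. Father sets are redrawn (up to 1000 attempts)
    until pairwise identifiable given the queen. Per-locus amplification
    failures blank both alleles at the configured rate.
    """
    config.validate()
    colony = config.colonies[colony_index]
    if colony.n_workers <= 0:
        raise ValueError("zero workers requested")
    rng = np.random.default_rng(seed)
    colony_id = f"C{colony_index + 1}"
    n_pat = len(colony.patriline_proportions)

    freqs = {
        locus.name: rng.dirichlet(
            np.full(locus.n_alleles, locus.frequency_concentration)
        )
        for locus in config.loci
    }
    locus_names = [locus.name for locus in config.loci]

    def draw_allele(name: str) -> int:
        return int(rng.choice(len(freqs[name]), p=freqs[name])) + 1

    queen_loci = {name: (draw_allele(name), draw_allele(name)) for name in locus_names}
    queen = MultilocusGenotype(f"{colony_id}-queen", colony_id, queen_loci)
    queen_alleles = {name: queen.alleles(name) for name in locus_names}

    fathers = None
    for _ in range(1000):
        candidate = [
            {name: draw_allele(name) for name in locus_names} for _ in range(n_pat)
        ]
        if _identifiable(candidate, queen_alleles):
            fathers = candidate
            break
    if fathers is None:
        raise ValueError(
            "could not draw pairwise-identifiable fathers; increase locus "
            "polymorphism"
        )

    width = len(str(colony.n_workers))
    workers: list[MultilocusGenotype] = []
    labels: dict[str, int] = {}
    pat_indices = rng.choice(
        n_pat, size=colony.n_workers, p=np.asarray(colony.patriline_proportions)
    )
    for w, pat in enumerate(pat_indices):
        specimen = f"{colony_id}-w{w + 1:0{width}d}"
        loci = {}
        for name in locus_names:
            maternal = queen_loci[name][rng.integers(2)]
            pair = (maternal, fathers[pat][name])
            if rng.random() < config.amplification_failure_rate:
                pair = (MISSING, MISSING)
            loci[name] = pair
        workers.append(MultilocusGenotype(specimen, colony_id, loci))
        labels[specimen] = int(pat)

    truth = ColonyTruth(
        colony_id=colony_id,
        queen_genotype=queen,
        father_haplotypes=fathers,
        worker_patriline_labels=labels,
        allele_frequencies=freqs,
    )
    return truth, workers


def _render_wing(
    tangent: np.ndarray,
    logcs: float,
    rng: np.random.Generator | None,
    randomize_pose: bool,
) -> np.ndarray:
    template, basis = _template_unit_and_basis()
    shape = template + (basis @ tangent).reshape(N_LANDMARKS, 2)
    coords = shape * np.exp(logcs)
    if randomize_pose and rng is not None:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        coords = coords @ np.array([[c, s], [-s, c]])
        coords = coords + rng.uniform(-2.0, 2.0, size=2) * np.exp(logcs)
    return coords


def sample_wings(
    truth: ColonyTruth,
    config: SimulationConfig,
    seed: int,
    allometry_direction: np.ndarray | None = None,
) -> WingDataset:
    """Simulate one observed wing per worker of a colony.

    True shape (template tangent space) = colony effect + patriline effect
    (fixed random unit direction x ``delta_patriline``) + shared allometric
    direction x ``allometry_magnitude`` x (logCS - grand mean) + isotropic
    individual noise. Log centroid size = grand mean + colony + patriline +
    individual deviates with the configured variances. The observed
    configuration adds mounting then digitization tangent noise, a random
    pose (unless ``randomize_pose`` is off), and a damage flag with the
    configured probability. Ground-truth effect vectors are recorded on
    ``truth``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    dim = template_tangent_basis().shape[1]
    size_m = config.size_model
    shape_m = config.shape_model
    n_pat = truth.n_patrilines

    if allometry_direction is None:
        allometry_direction = _unit_vector(rng, dim)
    colony_shape = shape_m.delta_colony * _unit_vector(rng, dim)
    pat_shape = shape_m.delta_patriline * np.stack(
        [_unit_vector(rng, dim) for _ in range(n_pat)]
    )
    colony_size = rng.normal(0.0, np.sqrt(size_m.var_colony))
    pat_size = rng.normal(0.0, np.sqrt(size_m.var_patriline), size=n_pat)

    truth.true_patriline_shape_effects = pat_shape
    truth.true_colony_shape_effect = colony_shape
    truth.true_allometry_direction = np.asarray(allometry_direction)
    truth.true_size_effects = {
        "colony": float(colony_size),
        "patriline": pat_size.copy(),
    }

    records = []
    for specimen in sorted(truth.worker_patriline_labels):
        pat = truth.worker_patriline_labels[specimen]
        logcs = (
            size_m.grand_mean_logcs
            + colony_size
            + pat_size[pat]
            + rng.normal(0.0, np.sqrt(size_m.var_individual))
        )
        tangent = (
            colony_shape
            + pat_shape[pat]
            + shape_m.allometry_magnitude
            * (logcs - size_m.grand_mean_logcs)
            * truth.true_allometry_direction
            + rng.normal(0.0, shape_m.sigma_individual, size=dim)
        )
        observed = (
            tangent
            + rng.normal(0.0, shape_m.sigma_mounting, size=dim)
            + rng.normal(0.0, shape_m.sigma_digitization, size=dim)
        )
        coords = _render_wing(observed, logcs, rng, config.randomize_pose)
        damaged = bool(rng.random() < config.damage_probability)
        records.append(
            WingRecord(
                specimen_id=specimen,
                colony_id=truth.colony_id,
                patriline_true=pat,
                logcs_true=float(logcs),
                tangent_true=tangent,
                config=LandmarkConfiguration(
                    coords, specimen_id=specimen, colony_id=truth.colony_id
                ),
                damaged=damaged,
            )
        )
    return WingDataset(records)


def replicate_measurements(
    wings: WingDataset, config: SimulationConfig, seed: int
) -> tuple[list[LandmarkConfiguration], dict[str, int]]:
    """Error-study dataset: re-measure selected wings under a nested design.

    The first ``n_specimens`` undamaged wings (canonical specimen order) are
    each mounted ``n_mountings`` times, and every mounting digitized
    ``n_digitizations`` times; each record carries (specimen, mounting,
    digitization) identifiers. Returns the landmark records plus each
    selected specimen's true patriline label.
    """
    design = config.error_study
    available = sorted(wings.measured(), key=lambda r: r.specimen_id)
    if design.n_specimens > len(available):
        raise ValueError(
            f"error study needs {design.n_specimens} specimens, only "
            f"{len(available)} undamaged wings available"
        )
    rng = np.random.default_rng(seed)
    dim = template_tangent_basis().shape[1]
    shape_m = config.shape_model

    records: list[LandmarkConfiguration] = []
    labels: dict[str, int] = {}
    for rec in available[: design.n_specimens]:
        labels[rec.specimen_id] = rec.patriline_true
        for mounting in range(1, design.n_mountings + 1):
            mount_noise = rng.normal(0.0, shape_m.sigma_mounting, size=dim)
            for digit in range(1, design.n_digitizations + 1):
                observed = (
                    rec.tangent_true
                    + mount_noise
                    + rng.normal(0.0, shape_m.sigma_digitization, size=dim)
                )
                coords = _render_wing(
                    observed, rec.logcs_true, rng, config.randomize_pose
                )
                records.append(
                    LandmarkConfiguration(
                        coords,
                        specimen_id=rec.specimen_id,
                        colony_id=rec.colony_id,
                        mounting=mounting,
                        digitization=digit,
                    )
                )
    return records, labels


@dataclass
class StudyData:
    """Everything one simulated study produces, with ground truth."""

    config: SimulationConfig
    truths: list[ColonyTruth]
    workers: list[MultilocusGenotype]
    queens: dict[str, MultilocusGenotype]
    wings: WingDataset
    error_records: list[LandmarkConfiguration]
    error_labels: dict[str, int]


def simulate_study(config: SimulationConfig, seed: int | None = None) -> StudyData:
    """Simulate the full study: every colony's pedigree and wings plus the
    measurement-error dataset (drawn from the first colony, as in the study
    design). A single allometric direction is shared across colonies."""
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    n_col = len(config.colonies)
    children = root.spawn(2 * n_col + 2)
    dim = template_tangent_basis().shape[1]
    allometry = _unit_vector(np.random.default_rng(children[0]), dim)

    truths: list[ColonyTruth] = []
    workers: list[MultilocusGenotype] = []
    queens: dict[str, MultilocusGenotype] = {}
    all_records: list[WingRecord] = []
    for i in range(n_col):
        truth, colony_workers = sample_pedigree(
            config, i, children[1 + 2 * i]
        )
        wings = sample_wings(
            truth, config, children[2 + 2 * i], allometry_direction=allometry
        )
        truths.append(truth)
        workers.extend(colony_workers)
        queens[truth.colony_id] = truth.queen_genotype
        all_records.extend(wings.records)

    first_colony = WingDataset(
        [r for r in all_records if r.colony_id == truths[0].colony_id]
    )
    error_records, error_labels = replicate_measurements(
        first_colony, config, children[-1]
    )
    return StudyData(
        config=config,
        truths=truths,
        workers=workers,
        queens=queens,
        wings=WingDataset(all_records),
        error_records=error_records,
        error_labels=error_labels,
    )
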