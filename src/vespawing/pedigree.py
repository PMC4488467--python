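"""Haplodiploid paternity assignment from multilocus microsatellite genotypes.

In haplodiploid Hymenoptera, males are haploid: every daughter of one father
receives the *same* paternal allele at every locus, plus one of her mother's
two alleles. Given the queen's genotype, each worker's paternal contribution
is therefore either pinned down exactly (the worker allele the queen does not
carry) or ambiguous between the worker's two alleles (when both are also
queen alleles). Workers are partitioned into patrilines by finding the
*minimum* number of paternal haplotypes jointly compatible with all workers,
by exact search with deterministic tie-breaking.

The module also implements the standard genotype quality filters (exclusion
of workers failing to amplify at more than one locus; the queen-compatibility
check) and the non-detection probability -- the chance that two random males
share a multilocus genotype, prod_j sum_i q_ij^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MISSING",
    "MultilocusGenotype",
    "AlleleFrequencyTable",
    "PatrilineAssignment",
    "filter_amplification",
    "check_maternity",
    "infer_patrilines",
    "non_detection_probability",
    "patriline_frequencies",
    "paternal_allele_frequencies",
]

#: Allele code meaning "did not amplify". A locus is missing iff both codes are 0.
MISSING = 0


@dataclass
class MultilocusGenotype:
    """Diploid allele pairs at named loci for one specimen (queen or worker).

    Allele pairs are canonicalized to ``(min, max)`` on construction; a locus
    is missing iff both codes are 0 (mixed 0/non-0 pairs are rejected).
    """

    specimen_id: str
    colony_id: str
    loci: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        canonical = {}
        for name, pair in self.loci.items():
            a, b = int(pair[0]), int(pair[1])
            if (a == MISSING) != (b == MISSING):
                raise ValueError(
                    f"{self.specimen_id}: locus {name} half-missing ({a},{b})"
                )
            canonical[name] = (min(a, b), max(a, b))
        self.loci = canonical

    def is_missing(self, locus: str) -> bool:
        return self.loci[locus] == (MISSING, MISSING)

    @property
    def n_missing(self) -> int:
        return sum(pair == (MISSING, MISSING) for pair in self.loci.values())

    def alleles(self, locus: str) -> set[int]:
        return set(self.loci[locus]) - {MISSING}


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies: ``freqs[locus][allele] = q``."""

    freqs: dict[str, dict[int, float]]

    def validate(self, tol: float = 1e-9) -> None:
        for locus, table in self.freqs.items():
            if any(q < 0 for q in table.values()):
                raise ValueError(f"locus {locus}: negative frequency")
            total = sum(table.values())
            if abs(total - 1.0) > tol:
                raise ValueError(
                    f"locus {locus}: frequencies sum to {total}, not 1"
                )


@dataclass
class PatrilineAssignment:
    """Worker -> patriline partition with inferred paternal haplotypes.

    ``labels`` maps included specimens to contiguous patriline labels
    starting at 1 (in order of first appearance along the canonical specimen
    ordering). ``haplotypes[label - 1]`` maps each locus to the set of
    paternal alleles still compatible with the whole patriline (``None`` if
    the locus is unconstrained). ``excluded`` maps dropped specimens to a
    reason (``"amplification-failure"`` or ``"maternity-mismatch"``).
    """

    labels: dict[str, int]
    haplotypes: list[dict[str, frozenset[int] | None]]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def n_patrilines(self) -> int:
        return len(self.haplotypes)

    def counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for label in self.labels.values():
            out[label] = out.get(label, 0) + 1
        return out


def filter_amplification(
    workers: list[MultilocusGenotype],
) -> tuple[list[MultilocusGenotype], list[MultilocusGenotype]]:
    """Drop workers that failed to amplify at more than one locus."""
    if not workers:
        raise ValueError("no workers supplied")
    retained = [w for w in workers if w.n_missing <= 1]
    excluded = [w for w in workers if w.n_missing > 1]
    return retained, excluded


def check_maternity(worker: MultilocusGenotype, queen: MultilocusGenotype) -> bool:
    """True iff the worker shares an allele with the queen at every locus
    non-missing in both."""
    if set(worker.loci) != set(queen.loci):
        raise ValueError("worker and queen genotyped at different loci")
    for locus in worker.loci:
        if worker.is_missing(locus) or queen.is_missing(locus):
            continue
        if not worker.alleles(locus) & queen.alleles(locus):
            return False
    return True


def _paternal_candidates(
    worker: MultilocusGenotype, queen: MultilocusGenotype
) -> dict[str, frozenset[int] | None]:
    """Per-locus set of alleles the worker's father may carry.

    ``None`` means unconstrained (missing data). If the worker carries one
    allele absent from the queen it must be paternal; if both worker alleles
    are queen alleles either may be paternal; two non-queen alleles violate
    maternity and raise.
    """
    out: dict[str, frozenset[int] | None] = {}
    for locus in queen.loci:
        if worker.is_missing(locus):
            out[locus] = None
            continue
        w = worker.alleles(locus)
        if queen.is_missing(locus):
            out[locus] = frozenset(w)
            continue
        non_queen = w - queen.alleles(locus)
        if len(non_queen) == 0:
            out[locus] = frozenset(w)
        elif len(non_queen) == 1:
            out[locus] = frozenset(non_queen)
        else:
            raise ValueError(
                f"specimen {worker.specimen_id}: no maternal allele at locus "
                f"{locus}; fails the maternity check"
            )
    return out


def _compatible(
    group: dict[str, frozenset[int] | None],
    profile: dict[str, frozenset[int] | None],
) -> dict[str, frozenset[int] | None] | None:
    """Intersect a group's running constraints with a worker profile."""
    merged = {}
    for locus, g in group.items():
        p = profile[locus]
        if g is None:
            merged[locus] = p
        elif p is None:
            merged[locus] = g
        else:
            inter = g & p
            if not inter:
                return None
            merged[locus] = inter
    return merged


def infer_patrilines(
    workers: list[MultilocusGenotype],
    queen: MultilocusGenotype,
    max_profiles: int = 256,
) -> PatrilineAssignment:
    """Partition workers into the minimum number of paternal sibships.

    Workers must already pass :func:`filter_amplification` and
    :func:`check_maternity` (violations raise, naming the specimen). Workers
    with identical candidate profiles are merged before the search (always
    safe: constraints are per-locus set intersections). The minimal partition
    is found by iterative deepening over the father count with a depth-first
    search that tries existing groups in order of creation -- yielding the
    lexicographically-first minimal partition along the canonical (sorted
    specimen id) ordering -- and is therefore deterministic and independent
    of input order.
    """
    if not workers:
        raise ValueError("no workers supplied")
    ordered = sorted(workers, key=lambda w: w.specimen_id)
    for w in ordered:
        if w.n_missing > 1:
            raise ValueError(
                f"specimen {w.specimen_id}: fails amplification filter"
            )
        if not check_maternity(w, queen):
            raise ValueError(
                f"specimen {w.specimen_id}: fails the maternity check"
            )

    profiles: list[dict[str, frozenset[int] | None]] = []
    members: list[list[str]] = []
    index: dict[tuple, int] = {}
    for w in ordered:
        profile = _paternal_candidates(w, queen)
        key = tuple(
            (locus, profile[locus] if profile[locus] is None else tuple(sorted(profile[locus])))
            for locus in sorted(profile)
        )
        if key in index:
            members[index[key]].append(w.specimen_id)
        else:
            index[key] = len(profiles)
            profiles.append(profile)
            members.append([w.specimen_id])
    if len(profiles) > max_profiles:
        raise ValueError(
            f"{len(profiles)} distinct paternal profiles exceed the exact-search "
            f"limit of {max_profiles}"
        )

    solution = None
    for k in range(1, len(profiles) + 1):
        solution = _search(profiles, k)
        if solution is not None:
            break
    assert solution is not None  # k = n_profiles always feasible
    group_constraints, assignment = solution

    labels: dict[str, int] = {}
    for profile_idx, group_idx in enumerate(assignment):
        for specimen in members[profile_idx]:
            labels[specimen] = group_idx + 1
    haplotypes = [dict(g) for g in group_constraints]
    return PatrilineAssignment(labels=labels, haplotypes=haplotypes)


def _search(profiles, k):
    """Depth-first first-fit search for a k-group compatible partition."""
    groups: list[dict] = []
    assignment = [-1] * len(profiles)

    def recurse(i: int) -> bool:
        if i == len(profiles):
            return True
        # prune: remaining profiles cannot open more groups than slots left
        for gi in range(len(groups)):
            merged = _compatible(groups[gi], profiles[i])
            if merged is not None:
                saved = groups[gi]
                groups[gi] = merged
                assignment[i] = gi
                if recurse(i + 1):
                    return True
                groups[gi] = saved
        if len(groups) < k:
            groups.append(dict(profiles[i]))
            assignment[i] = len(groups) - 1
            if recurse(i + 1):
                return True
            groups.pop()
        assignment[i] = -1
        return False

    if recurse(0):
        return [dict(g) for g in groups], list(assignment)
    return None


def non_detection_probability(freqs: AlleleFrequencyTable) -> float:
    """Probability that two random haploid males share a multilocus genotype:
    the product over loci of the summed squared allele frequencies."""
    freqs.validate()
    p = 1.0
    for table in freqs.freqs.values():
        p *= sum(q * q for q in table.values())
    return p


def patriline_frequencies(
    assignment: PatrilineAssignment, n_genotyped: int
) -> dict[int, float]:
    """Per-patriline percentage of the genotyped workers."""
    if n_genotyped <= 0:
        raise ValueError("n_genotyped must be positive")
    counts = assignment.counts()
    if sum(counts.values()) > n_genotyped:
        raise ValueError("assigned workers exceed n_genotyped")
    return {
        label: 100.0 * count / n_genotyped
        for label, count in sorted(counts.items())
    }


def paternal_allele_frequencies(
    assignments: list[PatrilineAssignment],
) -> AlleleFrequencyTable:
    """Allele frequencies from inferred paternal haplotypes.

    Each inferred father contributes one count per locus; when a father's
    allele is only narrowed to an ambiguity set, the count is split equally
    across the set; unconstrained loci contribute nothing.
    """
    counts: dict[str, dict[int, float]] = {}
    for assignment in assignments:
        for haplotype in assignment.haplotypes:
            for locus, alleles in haplotype.items():
                if alleles is None:
                    continue
                table = counts.setdefault(locus, {})
                w = 1.0 / len(alleles)
                for allele in alleles:
                    table[allele] = table.get(allele, 0.0) + w
    freqs = {
        locus: {a: c / sum(table.values()) for a, c in table.items()}
        for locus, table in counts.items()
    }
    out = AlleleFrequencyTable(freqs)
    out.validate()
    return out
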