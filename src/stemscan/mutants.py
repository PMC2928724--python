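"""Structural comparison of mutant constructs against a reference sequence.

For a length-preserving substitution mutant, both sequences are folded with
the partition function and compared on three axes:

* ``ddg_ensemble`` - the increase in ensemble free energy of folding
  (mutant minus reference; positive means the mutant ensemble is less
  stable).  MFE deltas are carried alongside as a secondary column.
* loss of pairing in the mutated region - whether the centroid (all pairs
  with probability > 0.5) of the mutant retains any pair touching the
  mutated interval.
* gained pairing - new centroid pairs, clustered into maximal helices, to
  surface alternative structures the mutation makes accessible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ComparisonError
from .folding import FoldConfig, centroid_pairs, partition
from .sequences import SequenceRecord


@dataclass(frozen=True)
class MutantComparison:
    """Outcome of folding a mutant against its reference sequence."""

    name: str
    region: tuple[int, int]
    ddg_ensemble: float
    ddg_mfe: float
    mutated_region_unpaired: bool
    lost_pairs: frozenset[tuple[int, int]]
    gained_pairs: frozenset[tuple[int, int]]
    endo_pairs: frozenset[tuple[int, int]]
    mutant_pairs: frozenset[tuple[int, int]]


@dataclass(frozen=True)
class Helix:
    """A maximal run of stacked pairs: (i..i', j'..j) with i+k paired to j-k."""

    outer: tuple[int, int]
    length: int

    @property
    def five_prime(self) -> tuple[int, int]:
        i, _ = self.outer
        return (i, i + self.length - 1)

    @property
    def three_prime(self) -> tuple[int, int]:
        _, j = self.outer
        return (j - self.length + 1, j)

    def describe(self) -> str:
        a = self.five_prime
        b = self.three_prime
        return f"+{a[0]}..+{a[1]} paired with +{b[0]}..+{b[1]} ({self.length} bp)"


def compare_construct(
    endo: SequenceRecord,
    mutant: SequenceRecord,
    region: tuple[int, int],
    config: FoldConfig | None = None,
    threshold: float = 0.5,
) -> MutantComparison:
    """Fold ``endo`` and ``mutant``, diff their centroids, report the energetics.

    ``region`` is the mutated 1-based inclusive interval in the records'
    shared coordinate frame.  The mutated region counts as unpaired when no
    centroid pair of the mutant has *either* endpoint inside it.
    """
    if len(endo) != len(mutant):
        raise ComparisonError(
            f"length mismatch: {endo.id} has {len(endo)} nt, {mutant.id} has {len(mutant)} nt "
            "(substitution mutants preserve length by design)"
        )
    start, end = region
    if not (endo.start <= start <= end <= endo.end):
        raise ComparisonError(f"region {start}..{end} outside {endo.start}..{endo.end}")
    config = config or FoldConfig()
    endo_fold = partition(endo, config)
    mut_fold = partition(mutant, config)
    endo_cent = centroid_pairs(endo_fold, threshold)
    mut_cent = centroid_pairs(mut_fold, threshold)
    lost = endo_cent.pairs - mut_cent.pairs
    gained = mut_cent.pairs - endo_cent.pairs
    unpaired = len(mut_cent.pairs_touching(start, end)) == 0
    return MutantComparison(
        name=mutant.id,
        region=region,
        ddg_ensemble=mut_fold.g_ensemble - endo_fold.g_ensemble,
        ddg_mfe=mut_fold.e_mfe - endo_fold.e_mfe,
        mutated_region_unpaired=unpaired,
        lost_pairs=frozenset(lost),
        gained_pairs=frozenset(gained),
        endo_pairs=endo_cent.pairs,
        mutant_pairs=mut_cent.pairs,
    )


def cluster_helices(pairs: frozenset[tuple[int, int]] | set[tuple[int, int]]) -> list[Helix]:
    """Group pairs into maximal helices: (i, j) stacks on (i+1, j-1)."""
    remaining = set(pairs)
    helices: list[Helix] = []
    while remaining:
        i, j = min(remaining)  # outermost pair of some helix after removal order
        while (i - 1, j + 1) in remaining:
            i, j = i - 1, j + 1
        length = 0
        a, b = i, j
        while (a, b) in remaining:
            remaining.discard((a, b))
            length += 1
            a, b = a + 1, b - 1
        helices.append(Helix(outer=(i, j), length=length))
    return sorted(helices, key=lambda h: h.outer)


def alternative_helix_report(comparison: MutantComparison) -> tuple[list[Helix], str]:
    """Cluster the gained pairs of a comparison into helices; plus prose summary."""
    helices = cluster_helices(comparison.gained_pairs)
    if not helices:
        return [], f"{comparison.name}: no gained base pairs"
    lines = [f"{comparison.name}: {len(helices)} alternative helix/helices gained:"]
    lines += [f"  - {h.describe()}" for h in helices]
    return helices, "\n".join(lines)
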