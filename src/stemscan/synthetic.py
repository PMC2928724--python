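"""Synthetic sequence generators with planted structural truth.

These generators emulate the statistical structure the scanner assumes in
real UTRs - G/C-rich backgrounds with controlled (di)nucleotide composition
and localised stable hairpins - so that every pipeline stage can be
exercised against a known ground truth without any external sequence.

A background is sampled either i.i.d. from mononucleotide frequencies or as
a first-order Markov chain matching target dinucleotide frequencies (the
same statistic the shuffle null preserves), starting from the chain's
stationary distribution.  A hairpin is planted by overwriting the
background with a perfect reverse-complementary stem of chosen length and
G/C fraction around an unpaired loop; the exact planted pair set is
returned as a truth annotation that round-trips through JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .sequences import SequenceRecord, apply_substitution, normalise_rna
from .shuffling import dinucleotide_counts, member_rng

BASES = "ACGU"


@dataclass(frozen=True)
class HairpinSpec:
    """A perfect stem of ``stem_length`` bp around a ``loop_length`` loop.

    ``position`` is the 1-based start of the 5' arm within the background;
    ``stem_gc_fraction`` is the fraction of G/C pairs in the stem.
    """

    stem_length: int
    loop_length: int = 4
    position: int = 1
    stem_gc_fraction: float = 1.0

    @property
    def span(self) -> int:
        return 2 * self.stem_length + self.loop_length

    def pair_set(self) -> frozenset[tuple[int, int]]:
        """The planted base pairs, 1-based in background coordinates."""
        p, s, l = self.position, self.stem_length, self.loop_length
        return frozenset((p + k, p + 2 * s + l - 1 - k) for k in range(s))


@dataclass(frozen=True)
class SyntheticSpec:
    """Length, composition target, optional planted hairpin, and seed."""

    length: int
    composition: dict = field(default_factory=lambda: {b: 0.25 for b in BASES})
    hairpin: HairpinSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        vals = list(self.composition.values())
        total = sum(float(v) for v in vals) if not _is_dinuc(self.composition) else None
        if total is not None:
            if any(v < 0 for v in vals) or abs(total - 1.0) > 1e-6:
                raise ValueError("mononucleotide frequencies must be non-negative and sum to 1")
        if self.hairpin is not None:
            if self.hairpin.position + self.hairpin.span - 1 > self.length:
                raise ValueError("hairpin does not fit inside the background length")


def _is_dinuc(composition: dict) -> bool:
    return any(len(str(k)) == 2 for k in composition)


def dinucleotide_frequencies(residues: str) -> dict[str, float]:
    """Empirical dinucleotide frequency table of a sequence."""
    counts = dinucleotide_counts(normalise_rna(residues))
    total = sum(counts.values())
    return {a + b: c / total for (a, b), c in counts.items()}


def _markov_from_dinuc(freqs: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrix and stationary distribution from dinucleotide targets."""
    T = np.zeros((4, 4))
    idx = {b: i for i, b in enumerate(BASES)}
    for k, v in freqs.items():
        a, b = normalise_rna(k)
        T[idx[a], idx[b]] = v
    rowsums = T.sum(axis=1)
    present = rowsums > 0
    T[present] /= rowsums[present, None]
    # stationary distribution of the chain restricted to reachable states
    marg = np.zeros(4)
    for k, v in freqs.items():
        a, _b = normalise_rna(k)
        marg[idx[a]] += v
    marg = marg / marg.sum()
    # verify the transition graph can sustain a long walk
    for i in range(4):
        if marg[i] > 0 and rowsums[i] == 0:
            raise ValueError(
                f"dinucleotide table is a dead end at {BASES[i]}: no outgoing transitions"
            )
    return T, marg


def random_background(spec: SyntheticSpec) -> tuple[SequenceRecord, dict]:
    """Sample a background sequence; returns (record, truth annotation).

    Mononucleotide compositions sample i.i.d.; dinucleotide compositions
    sample a first-order Markov chain started from the marginal
    distribution.  Identical specs (including seed) give identical output.
    """
    rng = member_rng(spec.seed, 7)
    if _is_dinuc(spec.composition):
        T, start = _markov_from_dinuc(spec.composition)
        out = np.empty(spec.length, dtype="U1")
        state = int(rng.choice(4, p=start))
        out[0] = BASES[state]
        for i in range(1, spec.length):
            row = T[state]
            if row.sum() == 0:
                raise ValueError("dinucleotide transition graph is disconnected")
            state = int(rng.choice(4, p=row))
            out[i] = BASES[state]
        residues = "".join(out)
    else:
        probs = np.array([float(spec.composition.get(b, 0.0)) for b in BASES])
        residues = "".join(rng.choice(list(BASES), size=spec.length, p=probs))
    record = SequenceRecord(
        id=f"synthetic-{spec.seed}",
        residues=residues,
        offset=1,
        source=f"synthetic background (seed {spec.seed})",
    )
    truth = {"spec": _spec_dict(spec), "planted_pairs": [], "planted_interval": None}
    if spec.hairpin is not None:
        record, truth = plant_hairpin(record, spec.hairpin, seed=spec.seed)
        truth["spec"] = _spec_dict(spec)
    return record, truth


def plant_hairpin(
    background: SequenceRecord, hairpin: HairpinSpec, seed: int = 0
) -> tuple[SequenceRecord, dict]:
    """Overwrite ``background`` with a perfect hairpin; returns (record, truth).

    The 5' arm is sampled at the requested G/C fraction, the 3' arm is its
    reverse complement, and the loop is adenine (unpairable against an A/U
    arm-free loop).  ``stem_length=0`` returns the background unchanged.
    """
    if hairpin.stem_length == 0:
        return background, {
            "planted_pairs": [],
            "planted_interval": None,
            "hairpin": asdict(hairpin),
        }
    p = hairpin.position
    if p < background.start or p + hairpin.span - 1 > background.end:
        raise ValueError(
            f"hairpin span {p}..{p + hairpin.span - 1} outside "
            f"{background.start}..{background.end}"
        )
    rng = member_rng(seed, 11)
    n_gc = int(round(hairpin.stem_gc_fraction * hairpin.stem_length))
    pair_types = ["GC" if i < n_gc else "AU" for i in range(hairpin.stem_length)]
    order = rng.permutation(hairpin.stem_length)
    # random pair orientation avoids homopolymeric arms (register slippage)
    arm5 = "".join(
        pair_types[i][int(rng.integers(2))] for i in order
    )
    arm3 = arm5.translate(str.maketrans("ACGU", "UGCA"))[::-1]
    loop = "A" * hairpin.loop_length
    lo = p - background.offset
    residues = (
        background.residues[:lo]
        + arm5
        + loop
        + arm3
        + background.residues[lo + hairpin.span :]
    )
    record = SequenceRecord(
        id=f"{background.id}+hp{hairpin.stem_length}bp@{p}",
        residues=residues,
        offset=background.offset,
        source=background.source,
    )
    truth = {
        "planted_pairs": sorted(hairpin.pair_set()),
        "planted_interval": [p, p + hairpin.span - 1],
        "hairpin": asdict(hairpin),
    }
    return record, truth


def make_mutant_series(
    seq: SequenceRecord, regions: list[tuple[int, int]], residue: str = "A"
) -> list[SequenceRecord]:
    """One substitution mutant per region, named ``<start>/<end><residue>``."""
    return [apply_substitution(seq, start, end, residue) for start, end in regions]


def _spec_dict(spec: SyntheticSpec) -> dict:
    d = {"length": spec.length, "composition": dict(spec.composition), "seed": spec.seed}
    d["hairpin"] = asdict(spec.hairpin) if spec.hairpin else None
    return d


def truth_to_json(truth: dict) -> str:
    return json.dumps(truth, indent=2, sort_keys=True)


def truth_from_json(text: str) -> dict:
    truth = json.loads(text)
    if truth.get("planted_pairs"):
        truth["planted_pairs"] = [tuple(p) for p in truth["planted_pairs"]]
    return truth
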