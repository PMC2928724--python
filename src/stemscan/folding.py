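"""RNA secondary-structure prediction behind a pluggable backend contract.

Two backends produce the same :class:`FoldResult`:

``thermodynamic``
    An adapter over the ViennaRNA library with its default Turner
    nearest-neighbour parameters.  This is the backend used to reproduce
    kcal/mol figures on real sequences.

``reference``
    The bespoke dynamic programs in :mod:`stemscan._reference` over a
    simplified nearest-neighbour model.  Exact by construction against an
    exhaustive enumeration of all nested structures at small n, and
    therefore the backend of choice for oracle-verified tests.

Energies are kcal/mol.  The ensemble free energy is ``-RT ln Z``; the
base-pair probability matrix holds the marginal probability that residues
``i`` and ``j`` pair in the Boltzmann ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from . import _reference
from .errors import ConfigError
from .sequences import SequenceRecord

GAS_CONSTANT = 0.0019872  # kcal/(mol K)

BACKENDS = ("thermodynamic", "reference")
PARAMETER_SETS = ("turner1999", "turner2004")


@dataclass(frozen=True)
class FoldConfig:
    """Folding parameters shared by both backends.

    ``temperature`` is in degrees Celsius (default 37, the standard folding
    convention); ``rt`` is the derived thermal energy k_B T in kcal/mol.

    ``parameter_set`` selects the nearest-neighbour table of the
    thermodynamic backend.  The default is the Turner 1999 set: it is the
    parameterisation of the era in which the TGF-beta1 5'UTR analysis was
    established, and the structural findings this package reproduces (e.g.
    complete loss of confident pairing in the ablation mutants) are
    parameterisation-sensitive at the margin.  ``turner2004`` selects the
    engine's modern default; energies then drift by a few percent.  The
    reference backend uses its own simplified model and ignores this field.
    """

    temperature: float = 37.0
    backend: str = "thermodynamic"
    parameter_set: str = "turner1999"
    min_hairpin_loop: int = 3
    reference_model: _reference.SimpleEnergyModel = field(
        default_factory=lambda: _reference.DEFAULT_MODEL
    )

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ConfigError(f"unknown backend {self.backend!r}; choose from {BACKENDS}")
        if self.backend == "thermodynamic" and self.parameter_set not in PARAMETER_SETS:
            raise ConfigError(
                f"unknown parameter set {self.parameter_set!r}; choose from {PARAMETER_SETS}"
            )
        if self.min_hairpin_loop < 3:
            raise ConfigError("min_hairpin_loop must be >= 3")
        if self.rt <= 0:
            raise ConfigError("temperature must exceed absolute zero")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * (self.temperature + 273.15)


@dataclass
class FoldResult:
    """MFE structure/energy and (after :func:`partition`) ensemble quantities.

    ``bppm`` is a symmetric ``n x n`` matrix indexed 0-based along the
    record; ``offset`` maps local index ``i`` to transcript position
    ``offset + i``.
    """

    id: str
    sequence: str
    offset: int
    mfe_structure: str
    e_mfe: float
    g_ensemble: float | None = None
    bppm: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def to_transcript(self, local_index: int) -> int:
        """Map a 0-based local index to the 1-based transcript position."""
        return self.offset + local_index


@dataclass(frozen=True)
class CentroidStructure:
    """Base pairs with probability above ``threshold``.

    Pair indices are 1-based transcript positions (the record's coordinate
    frame).  At threshold 0.5 no residue can appear in two pairs, since two
    pairs sharing a base cannot both exceed probability 0.5.
    """

    pairs: frozenset[tuple[int, int]]
    threshold: float
    min_pair_probability: float

    def pairs_within(self, start: int, end: int) -> frozenset[tuple[int, int]]:
        """Pairs with *both* endpoints inside the 1-based interval."""
        return frozenset((i, j) for i, j in self.pairs if start <= i <= end and start <= j <= end)

    def pairs_touching(self, start: int, end: int) -> frozenset[tuple[int, int]]:
        """Pairs with *either* endpoint inside the 1-based interval."""
        return frozenset(
            (i, j)
            for i, j in self.pairs
            if start <= i <= end or start <= j <= end
        )


_loaded_parameter_set: list[str | None] = [None]  # ViennaRNA params are process-global


def _vienna_compound(sequence: str, config: FoldConfig):
    import RNA

    if _loaded_parameter_set[0] != config.parameter_set:
        if config.parameter_set == "turner1999":
            RNA.params_load_RNA_Turner1999()
        else:
            RNA.params_load_RNA_Turner2004()
        _loaded_parameter_set[0] = config.parameter_set
    md = RNA.md()
    md.temperature = config.temperature
    return RNA.fold_compound(sequence, md)


def fold_mfe(seq: SequenceRecord, config: FoldConfig | None = None) -> FoldResult:
    """Minimum free energy over all pseudoknot-free structures, with witness.

    A sequence admitting no pair (too short, or no complementary residues)
    returns the open chain at 0.0 kcal/mol; that is a result, not an error.
    """
    config = config or FoldConfig()
    n = len(seq)
    if n < config.min_hairpin_loop + 2:
        return FoldResult(seq.id, seq.residues, seq.offset, "." * n, 0.0)
    if config.backend == "reference":
        e, structure = _reference.mfe_fold(seq.residues, config.reference_model)
        return FoldResult(seq.id, seq.residues, seq.offset, structure, e)
    fc = _vienna_compound(seq.residues, config)
    structure, e = fc.mfe()
    return FoldResult(seq.id, seq.residues, seq.offset, structure, float(e))


def partition(seq: SequenceRecord, config: FoldConfig | None = None) -> FoldResult:
    """Ensemble free energy -RT ln Z and base-pair probability matrix.

    The MFE fields are filled as well (the thermodynamic backend rescales
    its Boltzmann factors around the MFE for numerical stability, so the
    MFE fold is computed in either case).
    """
    config = config or FoldConfig()
    n = len(seq)
    if n < config.min_hairpin_loop + 2:
        return FoldResult(
            seq.id, seq.residues, seq.offset, "." * n, 0.0, 0.0, np.zeros((n, n))
        )
    if config.backend == "reference":
        e, structure = _reference.mfe_fold(seq.residues, config.reference_model)
        _z, g, bppm = _reference.partition_fold(seq.residues, config.rt, config.reference_model)
        return FoldResult(seq.id, seq.residues, seq.offset, structure, e, g, bppm)
    fc = _vienna_compound(seq.residues, config)
    structure, e = fc.mfe()
    fc.exp_params_rescale(e)
    _pf_structure, g = fc.pf()
    raw = np.asarray(fc.bpp())[1:, 1:]  # Vienna returns a 1-indexed upper triangle
    bppm = raw + raw.T
    return FoldResult(seq.id, seq.residues, seq.offset, structure, float(e), float(g), bppm)


def ensemble_energies(sequence: str, config: FoldConfig) -> tuple[float, float]:
    """(e_mfe, g_ensemble) for a bare sequence string; no BPPM is built.

    Internal fast path for window scans, where the probability matrix of
    every window would be wasted work.
    """
    n = len(sequence)
    if n < config.min_hairpin_loop + 2:
        return 0.0, 0.0
    if config.backend == "reference":
        e, _ = _reference.mfe_fold(sequence, config.reference_model)
        _z, g, _ = _reference.partition_fold(sequence, config.rt, config.reference_model)
        return e, g
    fc = _vienna_compound(sequence, config)
    _s, e = fc.mfe()
    fc.exp_params_rescale(e)
    _s2, g = fc.pf()
    return float(e), float(g)


def centroid_pairs(result: FoldResult, threshold: float = 0.5) -> CentroidStructure:
    """All base pairs with probability strictly above ``threshold``.

    Thresholds below 0.5 are rejected: two pairs sharing a residue could
    then both qualify and the pair set would no longer be a structure.
    """
    if threshold < 0.5:
        raise ConfigError(f"centroid threshold must be >= 0.5, got {threshold}")
    if result.bppm is None:
        raise ConfigError("FoldResult has no base-pair probability matrix; run partition() first")
    ii, jj = np.nonzero(np.triu(result.bppm) > threshold)
    pairs = frozenset(
        (result.to_transcript(int(i)), result.to_transcript(int(j))) for i, j in zip(ii, jj)
    )
    min_p = float(result.bppm[ii, jj].min()) if len(ii) else 1.0
    return CentroidStructure(pairs=pairs, threshold=threshold, min_pair_probability=min_p)


@dataclass(frozen=True)
class PairingProfile:
    """Per-window percent-paired series along a sequence.

    ``pct_discrete`` counts bases that participate in some individual pair
    with probability > 0.5; ``pct_weighted`` counts bases whose *total*
    pairing probability over all partners exceeds 0.5.
    """

    id: str
    window: int
    centres: np.ndarray
    pct_discrete: np.ndarray
    pct_weighted: np.ndarray

    def __len__(self) -> int:
        return len(self.centres)

    def rows(self) -> Iterator[tuple[int, float, float]]:
        yield from zip(self.centres.tolist(), self.pct_discrete.tolist(), self.pct_weighted.tolist())


def percent_paired_windows(result: FoldResult, window: int = 50) -> PairingProfile:
    """Percentage of paired bases in each fully contained ``window``."""
    if result.bppm is None:
        raise ConfigError("FoldResult has no base-pair probability matrix; run partition() first")
    n = len(result)
    if window > n:
        warnings.warn(f"window {window} exceeds sequence length {n}; empty profile")
        empty = np.array([])
        return PairingProfile(result.id, window, empty.astype(int), empty, empty)
    discrete = (result.bppm > 0.5).any(axis=1)
    weighted = result.bppm.sum(axis=1) > 0.5
    kernel = np.ones(window)
    d = np.convolve(discrete.astype(float), kernel, mode="valid") / window * 100.0
    w = np.convolve(weighted.astype(float), kernel, mode="valid") / window * 100.0
    starts = np.arange(n - window + 1)
    centres = result.offset + starts + (window - 1) // 2
    return PairingProfile(result.id, window, centres, d, w)
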