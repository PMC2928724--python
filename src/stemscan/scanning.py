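"""Sliding-window folding scans with dinucleotide-shuffled null models.

The core inference: slide windows of increasing size along a sequence in
single-nucleotide steps, fold each window (minimum free energy and ensemble
free energy), and compare the native energy against the distribution of
energies of dinucleotide-preserving scrambles of the same window.  The
segment score

    S = (E - mean(E_scrambled)) / sd(E_scrambled)

is a z-score: strongly negative values flag windows more stably folded than
their dinucleotide composition alone predicts.  A whole-sequence scramble
calibration (scan each full-length scramble and record its extreme score)
quantifies how often spikes of a given amplitude arise by composition alone.

Determinism: all randomness flows from one master seed through counter-based
sub-streams keyed by (window size, window start, member index), so profiles
are bitwise reproducible and independent of evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .errors import ConfigError
from .folding import FoldConfig, ensemble_energies
from .sequences import SequenceRecord
from .shuffling import dinucleotide_shuffle, make_null_set, member_rng

DEFAULT_SIZES = tuple(range(30, 101, 2))


def window_centre(start: int, size: int) -> int:
    """Reported centre of a window: left-of-middle for even sizes."""
    return start + (size - 1) // 2


@dataclass(frozen=True)
class WindowSpec:
    """Window lengths and stride of a scan (defaults: 30..100 step 2, stride 1)."""

    sizes: tuple[int, ...] = DEFAULT_SIZES
    stride: int = 1

    def __post_init__(self) -> None:
        if not self.sizes or min(self.sizes) < 2:
            raise ConfigError("all window sizes must be >= 2")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")

    def windows(self, seq_start: int, seq_end: int) -> Iterator[tuple[int, int]]:
        """(size, start) for every fully contained window, ordered by size then start."""
        for size in self.sizes:
            for start in range(seq_start, seq_end - size + 2, self.stride):
                yield size, start


@dataclass(frozen=True)
class SegmentScore:
    """Eq-style z-score of a native folding energy against its null set."""

    s: float
    e: float
    null_mean: float
    null_sd: float
    kind: str  # "mfe" | "ensemble"
    n_null: int
    degenerate: bool = False  # null sd was zero; s reported as 0


def segment_score(e: float, nulls: Sequence[float], kind: str = "ensemble") -> SegmentScore:
    """Score ``e`` against scramble energies ``nulls``.

    Uses the sample (n-1) standard deviation.  A degenerate null (sd = 0,
    e.g. a homopolymeric window) yields s = 0 with an explicit flag rather
    than an infinity, keeping profiles plottable and honest.
    """
    if len(nulls) == 0:
        raise ValueError("segment_score requires a non-empty null set")
    arr = np.asarray(nulls, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    if sd > 0.0:
        return SegmentScore((e - mean) / sd, e, mean, sd, kind, len(arr))
    return SegmentScore(0.0, e, mean, sd, kind, len(arr), degenerate=True)


@dataclass(frozen=True)
class WindowResult:
    """Energies and segment scores for one window, in transcript coordinates."""

    start: int
    size: int
    e_mfe: float
    g_ensemble: float
    score_mfe: SegmentScore | None
    score_ensemble: SegmentScore | None

    @property
    def centre(self) -> int:
        return window_centre(self.start, self.size)

    @property
    def g_per_nt(self) -> float:
        return self.g_ensemble / self.size


@dataclass(frozen=True)
class ScanProfile:
    """Ordered window results of one scan, with its provenance."""

    id: str
    spec: WindowSpec
    n_null: int
    seed: int
    results: tuple[WindowResult, ...]

    def __len__(self) -> int:
        return len(self.results)

    def for_size(self, size: int) -> tuple[WindowResult, ...]:
        return tuple(r for r in self.results if r.size == size)

    def minimum(self, size: int | None = None, key: Callable | None = None) -> WindowResult:
        """The window minimising ``key`` (default: ensemble energy per nucleotide)."""
        pool = self.results if size is None else self.for_size(size)
        if not pool:
            raise ConfigError("no windows in profile")
        return min(pool, key=key or (lambda r: r.g_per_nt))


def scan(
    seq: SequenceRecord,
    spec: WindowSpec | None = None,
    n_null: int = 100,
    seed: int = 0,
    config: FoldConfig | None = None,
) -> ScanProfile:
    """Fold every window of ``seq`` and score it against its own null set.

    The native window is folded once; its minimum and ensemble free energies
    share a single null set of ``n_null`` dinucleotide-preserving scrambles
    (each scramble is folded once for both energy kinds).  ``n_null=0``
    yields an energies-only profile with no scores.
    """
    spec = spec or WindowSpec()
    config = config or FoldConfig()
    if min(spec.sizes) > len(seq):
        raise ConfigError(
            f"all window sizes exceed sequence length {len(seq)}; empty profile"
        )
    results: list[WindowResult] = []
    for size, start in spec.windows(seq.start, seq.end):
        local = start - seq.offset
        window_seq = seq.residues[local : local + size]
        e_mfe, g_ens = ensemble_energies(window_seq, config)
        score_mfe = score_ens = None
        if n_null > 0:
            null_set = make_null_set(window_seq, n=n_null, seed=seed, stream=(size, start))
            null_e = np.empty(n_null)
            null_g = np.empty(n_null)
            for m, member in enumerate(null_set.members):
                null_e[m], null_g[m] = ensemble_energies(member, config)
            score_mfe = segment_score(e_mfe, null_e, kind="mfe")
            score_ens = segment_score(g_ens, null_g, kind="ensemble")
        results.append(WindowResult(start, size, e_mfe, g_ens, score_mfe, score_ens))
    return ScanProfile(id=seq.id, spec=spec, n_null=n_null, seed=seed, results=tuple(results))


def null_energy_profile(
    seq: SequenceRecord,
    spec: WindowSpec | None = None,
    n_null: int = 100,
    seed: int = 0,
    config: FoldConfig | None = None,
) -> list[tuple[int, float]]:
    """Per-centre mean scramble ensemble free energy per nucleotide.

    The dashed-line companion of the native energy profile: for each window,
    the mean over its null set of ensemble free energy divided by window
    size.  Uses the same per-window sub-streams as :func:`scan`, so the two
    series describe the same nulls.
    """
    if n_null < 1:
        raise ValueError("null_energy_profile requires n_null >= 1")
    profile = scan(seq, spec, n_null=n_null, seed=seed, config=config)
    return [(r.centre, r.score_ensemble.null_mean / r.size) for r in profile.results]


@dataclass(frozen=True)
class CalibrationResult:
    """Whole-sequence scramble calibration of extreme segment scores."""

    native_min: float
    scramble_mins: tuple[float, ...]
    kind: str
    window: int

    @property
    def native_quantile(self) -> float:
        """Empirical fraction of scramble minima at or below the native minimum."""
        arr = np.asarray(self.scramble_mins)
        return float((arr <= self.native_min).mean())


def calibrate_with_scrambles(
    seq: SequenceRecord,
    n_scrambles: int = 100,
    window: int = 50,
    n_null: int = 100,
    seed: int = 0,
    config: FoldConfig | None = None,
    kind: str = "ensemble",
) -> CalibrationResult:
    """Scan whole-sequence scrambles and collect their minimum segment scores.

    Each of ``n_scrambles`` dinucleotide-preserving scrambles of the entire
    sequence is subjected to the same ``window``-nt scan as the native
    sequence; the minimum segment score of each scan is recorded.  The
    native minimum's empirical quantile within that distribution says
    whether the native spike amplitude is at all unusual for the sequence's
    dinucleotide composition.
    """
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be >= 1")
    spec = WindowSpec(sizes=(window,))

    def min_score(record: SequenceRecord, scan_seed: int) -> float:
        profile = scan(record, spec, n_null=n_null, seed=scan_seed, config=config)
        attr = "score_mfe" if kind == "mfe" else "score_ensemble"
        return min(getattr(r, attr).s for r in profile.results)

    native_min = min_score(seq, seed)
    mins = []
    for t in range(n_scrambles):
        rng = member_rng(seed, 1, t)  # stream key 1: whole-sequence scrambles
        scrambled = SequenceRecord(
            id=f"{seq.id}|scramble{t}",
            residues=dinucleotide_shuffle(seq.residues, rng),
            offset=seq.offset,
        )
        mins.append(min_score(scrambled, seed))
    return CalibrationResult(
        native_min=native_min, scramble_mins=tuple(mins), kind=kind, window=window
    )
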