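"""Bespoke folding dynamic programs over a simplified nearest-neighbour model.

This backend exists so the folding algorithmics are owned and verifiable by
exhaustive enumeration at small n; the full Turner parameterisation of the
thermodynamic backend is deliberately not reproduced here.

Model (all energies kcal/mol, loop penalties positive, stacks negative):

* allowed pairs: AU, UA, GC, CG, GU, UG; minimum hairpin loop 3 unpaired;
* a *stack* of two adjacent pairs contributes minus the mean of the two
  pairs' strengths (GC 3.3, AU 2.1, GU 1.4);
* every hairpin loop costs ``hairpin_penalty``; every non-stack two-pair
  (interior/bulge) loop costs ``internal_penalty`` and may hold at most
  ``max_interior`` unpaired residues; every multiloop costs
  ``multiloop_penalty`` regardless of branch count;
* the exterior loop is free; unpaired residues are free everywhere.

Lone pairs are allowed (a hairpin-closing pair scores just the hairpin
penalty).  The energy of a structure is the sum over the loops closed by its
pairs, which is exactly what the enumeration oracle in the test-suite
recomputes independently.

Recursions are the standard Zuker (min-plus) and McCaskill (sum-product)
forms with arrays V/WM/WM2/W and Qb/Qm/Qe; base-pair probabilities come from
the outside pass.  Complexity is O(n^3)-O(n^4) in pure Python, intended for
short sequences (oracle tests, planted toy hairpins), not for genome-scale
scans - those go through the thermodynamic backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

INF = float("inf")

_PAIR_STRENGTH = {
    ("G", "C"): 3.3,
    ("C", "G"): 3.3,
    ("A", "U"): 2.1,
    ("U", "A"): 2.1,
    ("G", "U"): 1.4,
    ("U", "G"): 1.4,
}


@dataclass(frozen=True)
class SimpleEnergyModel:
    hairpin_penalty: float = 5.0
    internal_penalty: float = 3.0
    multiloop_penalty: float = 4.0
    min_hairpin_loop: int = 3
    max_interior: int = 30
    pair_strength: dict = field(default_factory=lambda: dict(_PAIR_STRENGTH))

    def pairable(self, a: str, b: str) -> bool:
        return (a, b) in self.pair_strength

    def stack_energy(self, outer: tuple[str, str], inner: tuple[str, str]) -> float:
        return -(self.pair_strength[outer] + self.pair_strength[inner]) / 2.0


DEFAULT_MODEL = SimpleEnergyModel()


def _can_pair(seq: str, i: int, j: int, model: SimpleEnergyModel) -> bool:
    return j - i > model.min_hairpin_loop and model.pairable(seq[i], seq[j])


def _two_pair_loop_energy(
    seq: str, i: int, j: int, k: int, l: int, model: SimpleEnergyModel
) -> float:
    """Energy of the loop closed by (i,j) with single inner pair (k,l), or +inf."""
    unpaired = (k - i - 1) + (j - l - 1)
    if unpaired == 0:
        return model.stack_energy((seq[i], seq[j]), (seq[k], seq[l]))
    if unpaired <= model.max_interior:
        return model.internal_penalty
    return INF


def mfe_fold(seq: str, model: SimpleEnergyModel = DEFAULT_MODEL) -> tuple[float, str]:
    """Minimum free energy and one witness dot-bracket structure."""
    n = len(seq)
    if n == 0:
        return 0.0, ""
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)   # >=1 branch in [i, j]
    WM2 = np.full((n, n), INF)  # >=2 branches in [i, j]

    for span in range(model.min_hairpin_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if _can_pair(seq, i, j, model):
                best = model.hairpin_penalty
                for k in range(i + 1, j):
                    for l in range(k + model.min_hairpin_loop + 1, j):
                        if V[k, l] == INF:
                            continue
                        w = _two_pair_loop_energy(seq, i, j, k, l, model)
                        if w < INF:
                            best = min(best, V[k, l] + w)
                if i + 1 <= j - 1 and WM2[i + 1, j - 1] < INF:
                    best = min(best, model.multiloop_penalty + WM2[i + 1, j - 1])
                V[i, j] = best
            # WM / WM2 over [i, j]
            wm = WM[i, j - 1] if j - 1 >= i else INF
            wm2 = WM2[i, j - 1] if j - 1 >= i else INF
            for k in range(i, j):
                if V[k, j] == INF:
                    continue
                one = V[k, j]
                wm = min(wm, one)
                if k - 1 >= i:
                    if WM[i, k - 1] < INF:
                        wm = min(wm, one + WM[i, k - 1])
                        wm2 = min(wm2, one + WM[i, k - 1])
            WM[i, j] = wm
            WM2[i, j] = wm2

    W = np.zeros(n + 1)  # W[j] = MFE of prefix seq[0:j]
    for j in range(1, n + 1):
        best = W[j - 1]
        for k in range(0, j):
            if V[k, j - 1] < INF:
                best = min(best, W[k] + V[k, j - 1])
        W[j] = best

    structure = ["."] * n
    _traceback_exterior(seq, V, WM, WM2, W, n, structure, model)
    return float(W[n]), "".join(structure)


def _traceback_exterior(seq, V, WM, WM2, W, n, structure, model):
    j = n
    eps = 1e-9
    while j > 0:
        if abs(W[j] - W[j - 1]) < eps:
            j -= 1
            continue
        for k in range(0, j):
            if V[k, j - 1] < INF and abs(W[j] - (W[k] + V[k, j - 1])) < eps:
                _traceback_pair(seq, V, WM, WM2, k, j - 1, structure, model)
                j = k
                break
        else:  # pragma: no cover - numerical safety net
            j -= 1


def _traceback_pair(seq, V, WM, WM2, i, j, structure, model):
    structure[i], structure[j] = "(", ")"
    eps = 1e-9
    e = V[i, j]
    if abs(e - model.hairpin_penalty) < eps:
        return
    for k in range(i + 1, j):
        for l in range(k + model.min_hairpin_loop + 1, j):
            if V[k, l] == INF:
                continue
            w = _two_pair_loop_energy(seq, i, j, k, l, model)
            if w < INF and abs(e - (V[k, l] + w)) < eps:
                _traceback_pair(seq, V, WM, WM2, k, l, structure, model)
                return
    if i + 1 <= j - 1 and WM2[i + 1, j - 1] < INF:
        if abs(e - (model.multiloop_penalty + WM2[i + 1, j - 1])) < eps:
            _traceback_multi(seq, V, WM, WM2, i + 1, j - 1, structure, model, branches=2)
            return
    raise AssertionError("traceback failed")  # pragma: no cover


def _traceback_multi(seq, V, WM, WM2, i, j, structure, model, branches):
    """Trace a region known to hold >=branches branches (branches in {1, 2})."""
    eps = 1e-9
    arr = WM2 if branches == 2 else WM
    e = arr[i, j]
    if j - 1 >= i and abs(arr[i, j - 1] - e) < eps:
        _traceback_multi(seq, V, WM, WM2, i, j - 1, structure, model, branches)
        return
    for k in range(i, j):
        if V[k, j] == INF:
            continue
        if branches == 1 and abs(e - V[k, j]) < eps:
            _traceback_pair(seq, V, WM, WM2, k, j, structure, model)
            return
        if k - 1 >= i and WM[i, k - 1] < INF and abs(e - (V[k, j] + WM[i, k - 1])) < eps:
            _traceback_pair(seq, V, WM, WM2, k, j, structure, model)
            _traceback_multi(seq, V, WM, WM2, i, k - 1, structure, model, branches=1)
            return
    raise AssertionError("multiloop traceback failed")  # pragma: no cover


def partition_fold(
    seq: str, rt: float, model: SimpleEnergyModel = DEFAULT_MODEL
) -> tuple[float, float, np.ndarray]:
    """Partition function Z, ensemble free energy -RT ln Z, and the BPPM.

    The matrix entry ``[i, j]`` (0-based) is the marginal probability that
    residues i and j pair in the Boltzmann ensemble at thermal energy ``rt``.
    """
    n = len(seq)
    bppm = np.zeros((n, n))
    if n == 0:
        return 1.0, 0.0, bppm

    beta = 1.0 / rt
    wh = math.exp(-beta * model.hairpin_penalty)
    wml = math.exp(-beta * model.multiloop_penalty)

    Qb = np.zeros((n, n))  # [i, j] paired
    Qm = np.zeros((n, n))  # >=1 branch in [i, j], unpaired residues free

    for span in range(model.min_hairpin_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if _can_pair(seq, i, j, model):
                q = wh
                for k in range(i + 1, j):
                    for l in range(k + model.min_hairpin_loop + 1, j):
                        if Qb[k, l] == 0.0:
                            continue
                        w = _two_pair_loop_energy(seq, i, j, k, l, model)
                        if w < INF:
                            q += Qb[k, l] * math.exp(-beta * w)
                # multiloop: first branch (k, l), >=1 further branch right of it
                acc = 0.0
                for k in range(i + 1, j - 1):
                    for l in range(k + model.min_hairpin_loop + 1, j - 1):
                        if Qb[k, l] and Qm[l + 1, j - 1]:
                            acc += Qb[k, l] * Qm[l + 1, j - 1]
                q += wml * acc
                Qb[i, j] = q
            # Qm: first branch (k, l) with i..k-1 unpaired
            acc = 0.0
            for k in range(i, j):
                for l in range(k + model.min_hairpin_loop + 1, j + 1):
                    if Qb[k, l]:
                        rest = Qm[l + 1, j] if l + 1 <= j else 0.0
                        acc += Qb[k, l] * (1.0 + rest)
            Qm[i, j] = acc

    # exterior, left-to-right and right-to-left
    Qe = np.ones(n + 1)  # Qe[j]: prefix seq[0:j]
    for j in range(1, n + 1):
        q = Qe[j - 1]
        for k in range(0, j):
            if Qb[k, j - 1]:
                q += Qe[k] * Qb[k, j - 1]
        Qe[j] = q
    Qs = np.ones(n + 1)  # Qs[i]: suffix seq[i:n]
    for i in range(n - 1, -1, -1):
        q = Qs[i + 1]
        for l in range(i, n):
            if Qb[i, l]:
                q += Qb[i, l] * Qs[l + 1]
        Qs[i] = q
    Z = Qe[n]

    # outside pass, decreasing span
    Qout = np.zeros((n, n))
    spans = range(n - 1, model.min_hairpin_loop, -1)
    for span in spans:
        for i in range(0, n - span):
            j = i + span
            if Qb[i, j] == 0.0:
                continue
            out = Qe[i] * Qs[j + 1]
            for k in range(0, i):
                for l in range(j + 1, n):
                    if Qout[k, l] == 0.0 or not _can_pair(seq, k, l, model):
                        continue
                    w = _two_pair_loop_energy(seq, k, l, i, j, model)
                    if w < INF:
                        out += Qout[k, l] * math.exp(-beta * w)
                    qm_left = Qm[k + 1, i - 1] if k + 1 <= i - 1 else 0.0
                    qm_right = Qm[j + 1, l - 1] if j + 1 <= l - 1 else 0.0
                    extra = qm_left * (1.0 + qm_right) + qm_right
                    if extra:
                        out += Qout[k, l] * wml * extra
            Qout[i, j] = out
            p = Qb[i, j] * out / Z
            bppm[i, j] = bppm[j, i] = p

    g = -rt * math.log(Z)
    return float(Z), float(g), bppm
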