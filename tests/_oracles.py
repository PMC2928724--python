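"""Independent oracles used by the test suite.

Everything in here is deliberately naive - exhaustive enumeration, direct
string manipulation, per-character tallies - and shares no code path with
the package implementation it checks.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

INF = float("inf")


# --- exhaustive structure enumeration over the simplified energy model ----


def enumerate_structures(seq: str, model) -> list[list[tuple[int, int]]]:
    """All pseudoknot-free pair sets over ``seq`` (0-based pairs, incl. empty)."""
    n = len(seq)
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i + model.min_hairpin_loop + 1, n)
        if model.pairable(seq[i], seq[j])
    ]
    out: list[list[tuple[int, int]]] = []

    def extend(chosen: list, used: set, idx: int) -> None:
        out.append(list(chosen))
        for t in range(idx, len(candidates)):
            i, j = candidates[t]
            if i in used or j in used:
                continue
            if any(a < i < b < j or i < a < j < b for a, b in chosen):
                continue  # crossing == pseudoknot
            chosen.append((i, j))
            used.update((i, j))
            extend(chosen, used, t + 1)
            chosen.pop()
            used.difference_update((i, j))

    extend([], set(), 0)
    return out


def structure_energy(seq: str, pairs: list[tuple[int, int]], model) -> float:
    """Loop-decomposition energy of one structure; +inf if a loop is illegal."""
    if not pairs:
        return 0.0
    pmap = dict(sorted(pairs))
    total = 0.0
    for i, j in pairs:
        inner: list[tuple[int, int]] = []
        k = i + 1
        while k < j:
            if k in pmap and k < pmap[k] < j:
                inner.append((k, pmap[k]))
                k = pmap[k] + 1
            else:
                k += 1
        if not inner:
            total += model.hairpin_penalty
        elif len(inner) == 1:
            k, l = inner[0]
            unpaired = (k - i - 1) + (j - l - 1)
            if unpaired == 0:
                total += model.stack_energy((seq[i], seq[j]), (seq[k], seq[l]))
            elif unpaired <= model.max_interior:
                total += model.internal_penalty
            else:
                return INF
        else:
            total += model.multiloop_penalty
    return total


def brute_force_fold(seq: str, rt: float, model):
    """(e_mfe, Z, bppm) by full enumeration with Boltzmann weighting."""
    n = len(seq)
    structures = enumerate_structures(seq, model)
    energies = [structure_energy(seq, s, model) for s in structures]
    e_min = min(energies)
    z = 0.0
    bppm = np.zeros((n, n))
    for pairs, e in zip(structures, energies):
        if e == INF:
            continue
        w = math.exp(-e / rt)
        z += w
        for i, j in pairs:
            bppm[i, j] += w
            bppm[j, i] += w
    return e_min, z, bppm / z


def dotbracket_pairs(structure: str) -> set[tuple[int, int]]:
    """0-based pair set of a dot-bracket string."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for idx, c in enumerate(structure):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            pairs.add((stack.pop(), idx))
    assert not stack, "unbalanced dot-bracket"
    return pairs


# --- sequence-level oracles ----------------------------------------------


def pair_count_table(seq: str) -> Counter:
    """Dinucleotide counts by an explicit position loop."""
    table: Counter = Counter()
    for pos in range(len(seq) - 1):
        table[seq[pos : pos + 2]] += 1
    return table


def naive_fasta_scan(text: str) -> list[tuple[str, str]]:
    """Character-by-character FASTA parse, upper-cased, T->U."""
    entries: list[tuple[str, str]] = []
    name, buf = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                entries.append((name, "".join(buf)))
            name, buf = line[1:].split()[0], []
        elif line.strip():
            buf.append(line.strip().upper().replace("T", "U"))
    if name is not None:
        entries.append((name, "".join(buf)))
    return entries
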