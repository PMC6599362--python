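"""Stem-loop folding and thermodynamic statistics of candidate precursors.

Folding goes through the ViennaRNA library: locally stable structures from
the sliding-window MFE scanner (the RNALfold algorithm), free energies of
fixed structures from the Matthews-Turner nearest-neighbor model (RNAeval).

Three interrelated stability statistics are attached to each hairpin:

* MFE   — minimum free energy of the structure, kcal/mol;
* AMFE  — MFE normalized per 100 nt, so precursors of different lengths
          are comparable;
* MFEI  — AMFE divided by the GC percentage; genuine pre-miRNAs are both
          stable and not merely GC-rich, which pushes MFEI strongly
          negative (the bulk of known plant precursors sit below -0.6).

Significance of the observed stability can additionally be assessed against
random sequences with identical dinucleotide composition (Altschul-Erickson
shuffling), since nearest-neighbor energies are a function of dinucleotides.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import RNA

from .model import Hairpin, ShuffleResult

logger = logging.getLogger(__name__)

_VALID = set("ACGU")


def fold_locally(
    sequence: str, max_span: int = 350
) -> list[tuple[str, float, int]]:
    """Locally stable secondary structures of ``sequence``.

    Runs the ViennaRNA sliding-window MFE scan with window size
    ``max_span`` and returns ``(structure, mfe, local_start)`` tuples with
    0-based start offsets.
    """
    seq = sequence.upper()
    if set(seq) - _VALID:
        raise ValueError(
            f"invalid characters in sequence: {sorted(set(seq) - _VALID)}"
        )
    if len(seq) < 40:
        raise ValueError(f"sequence too short to fold locally ({len(seq)} nt)")
    md = RNA.md()
    md.window_size = min(len(seq), max_span)
    md.max_bp_span = min(len(seq), max_span)
    fc = RNA.fold_compound(seq, md, RNA.OPTION_WINDOW)
    hits: list[tuple[str, float, int]] = []

    def _cb(start: int, end: int, structure: str, energy: float, data) -> None:
        # ViennaRNA reports 1-based start positions
        data.append((structure.strip(), float(energy), start - 1))

    fc.mfe_window_cb(_cb, hits)
    return [h for h in hits if h[1] < 0.0]


def pair_table(structure: str) -> list[int]:
    """0-based pair table: ``pt[i]`` = partner of ``i`` or -1 if unpaired."""
    raw = RNA.ptable(structure)  # 1-based, raw[0] is the length
    return [raw[i + 1] - 1 for i in range(len(structure))]


def _stem_components(structure: str) -> list[tuple[int, int]]:
    """Maximal single-stem segments, one per terminal loop.

    A segment starts at a terminal (hairpin) loop's closing pair and is
    extended outward through stacked pairs, bulges and interior loops for as
    long as each enclosing pair encloses only this branch.  Multiloops are
    thereby dissolved into their branches.
    """
    pt = pair_table(structure)
    n = len(structure)
    segments = []
    i = 0
    while i < n:
        j = pt[i]
        if j > i:
            inner = structure[i + 1 : j]
            if "(" not in inner and ")" not in inner:
                # terminal loop closed by (i, j); extend outward
                lo, hi = i, j
                while True:
                    k = lo - 1
                    while k >= 0 and pt[k] == -1:
                        k -= 1
                    if k < 0 or pt[k] < k:
                        break
                    m = pt[k]
                    # single-stem only if nothing pairs between hi and m
                    if m <= hi or any(pt[x] != -1 for x in range(hi + 1, m)):
                        break
                    lo, hi = k, m
                segments.append((lo, hi + 1))
        i += 1
    return segments


def select_stemloop(
    sequence: str,
    folds: list[tuple[str, float, int]],
    min_len: int = 60,
    max_len: int = 350,
    min_paired_frac: float = 0.5,
) -> Hairpin | None:
    """Pick the best miRNA-compatible stem-loop among locally stable folds.

    Candidate stem-loops are single-terminal-loop components of each fold
    (external unpaired tails trimmed, multiloops dissolved), kept when their
    length lies in ``[min_len, max_len]`` and at least ``min_paired_frac``
    of their bases are paired.  The hairpin with the lowest evaluated free
    energy wins.  Returned coordinates (``start``/``end``) are local to
    ``sequence``; the caller rebases them onto the genome.
    """
    best: Hairpin | None = None
    best_mfe = np.inf
    for structure, _, local_start in folds:
        for lo, hi in _stem_components(structure):
            length = hi - lo
            if not (min_len <= length <= max_len):
                continue
            sub_struct = structure[lo:hi]
            paired = sum(1 for c in sub_struct if c != ".")
            if paired / length < min_paired_frac:
                continue
            g_lo = local_start + lo
            sub_seq = sequence[g_lo : g_lo + length].upper()
            mfe = evaluate_structure(sub_seq, sub_struct)
            if mfe >= 0 or mfe >= best_mfe:
                continue
            hp = Hairpin(
                chrom="",
                strand="+",
                start=g_lo,
                end=g_lo + length,
                sequence=sub_seq,
                structure=sub_struct,
                mfe=mfe,
            )
            _set_arms(hp)
            best, best_mfe = hp, mfe
    return best


def _set_arms(hp: Hairpin) -> None:
    pt = pair_table(hp.structure)
    paired = [i for i, p in enumerate(pt) if p != -1]
    # innermost pair flanks the single terminal loop
    inner_open = max(i for i in paired if pt[i] > i)
    loop = (inner_open + 1, pt[inner_open])
    hp.arm5 = (0, loop[0])
    hp.loop = loop
    hp.arm3 = (loop[1], len(hp.structure))


def evaluate_structure(sequence: str, structure: str) -> float:
    """Free energy (kcal/mol) of a fixed structure, nearest-neighbor model."""
    fc = RNA.fold_compound(sequence)
    return float(fc.eval_structure(structure))


def thermo_stats(hairpin: Hairpin) -> Hairpin:
    """Populate mfe, amfe, mfei and gc_percent in place (and return it)."""
    seq = hairpin.sequence.upper()
    n = len(seq)
    hairpin.mfe = evaluate_structure(seq, hairpin.structure)
    hairpin.gc_percent = 100.0 * (seq.count("G") + seq.count("C")) / n
    hairpin.amfe = hairpin.mfe / n * 100.0
    if hairpin.gc_percent == 0.0:
        raise ValueError("MFEI undefined for a GC-free sequence")
    hairpin.mfei = hairpin.amfe / hairpin.gc_percent
    return hairpin


def mfei_prefilter(
    hairpins: list[Hairpin], threshold: float = -0.6, enabled: bool = True
) -> list[Hairpin]:
    """Keep hairpins with MFEI strictly below ``threshold`` (when enabled)."""
    if not enabled:
        return list(hairpins)
    return [h for h in hairpins if h.mfei < threshold]


# ---------------------------------------------------------------------------
# dinucleotide shuffle


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Random permutation of ``sequence`` preserving all dinucleotide counts.

    Altschul-Erickson Eulerian-path method: the sequence is a walk on the
    graph whose edges are its dinucleotides; any Eulerian path with the same
    start and end vertices is an exact-dinucleotide shuffle.  A random such
    path is drawn by fixing a uniformly chosen in-tree toward the final
    vertex (the path's last-exit edges) and shuffling all remaining edges.
    """
    s = sequence.upper()
    if len(s) < 4:
        raise ValueError(f"sequence too short to shuffle ({len(s)} nt)")
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    vertices = [v for v in edges if v != s[-1]]

    for _ in range(10_000):
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        if _is_in_tree(last_exit, s[-1]):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to sample a connected last-exit tree")

    rest: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in last_exit:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        rest[v] = pool

    out = [s[0]]
    v = s[0]
    while True:
        if rest[v]:
            nxt = rest[v].pop(0)
        elif v in last_exit:
            nxt = last_exit.pop(v)
        else:
            break
        out.append(nxt)
        v = nxt
    return "".join(out)


def _is_in_tree(last_exit: dict[str, str], root: str) -> bool:
    for v in last_exit:
        seen = set()
        while v != root:
            if v in seen or v not in last_exit:
                return False
            seen.add(v)
            v = last_exit[v]
    return True


def shuffle_significance(
    hairpin: Hairpin | str, n: int = 100, seed: int | None = None
) -> ShuffleResult:
    """Empirical stability p-value against dinucleotide-preserving shuffles.

    The observed sequence and each of ``n`` shuffles are folded globally;
    the pseudocount-corrected empirical p-value is
    ``(#shuffles with MFE <= observed + 1) / (n + 1)``.
    """
    if n < 10:
        raise ValueError(f"need at least 10 shuffles, got {n}")
    seq = hairpin if isinstance(hairpin, str) else hairpin.sequence
    seq = seq.upper()
    rng = np.random.default_rng(seed)
    _, observed = RNA.fold(seq)
    n_as_stable = 0
    for _ in range(n):
        shuf = dinucleotide_shuffle(seq, rng)
        _, mfe = RNA.fold(shuf)
        if mfe <= observed:
            n_as_stable += 1
    return ShuffleResult(
        n_shuffles=n,
        n_as_stable=n_as_stable,
        empirical_p=(n_as_stable + 1) / (n + 1),
    )
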