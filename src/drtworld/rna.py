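"""RNA polymer events: random ligation, template-directed replication with
mutation, strand separation, degradation, and functional-motif recognition.

Replication is two-stage: a template attracts substrates (monomers or
oligomers) by base-pairing with mutation rate ``P_FP`` per base, aligned
segments are ligated with ``P_TL``, and segments separate with
``P_SP**sqrt(n)``.  The complement is stored in template coordinates; a
released complement reads reversed, so functional motifs (recognized on
the sense strand only) reappear only after a second round of copying.

Per-entity Bernoulli decisions draw from the world's buffered uniform
stream; counts of i.i.d. events per strand are sampled by exact
inverse-CDF binomial inversion of a single uniform, which keeps the event
distributions identical to naive per-bond coin flips at a fraction of the
cost.
"""

from __future__ import annotations

import math
from typing import List, Optional, Set, Tuple

import numpy as np

from .config import BASES, BASE_INDEX, Params, SequenceDefs, WC
from .world import RNAStrand, World

_WC_INDEX = {0: 3, 3: 0, 1: 2, 2: 1}  # A<->U, C<->G in BASES order

#: memoized mismatch counts for (template, substrate, offset) triples
_MISMATCH_CACHE: dict = {}


# --------------------------------------------------------------------------
# Probability kernels
# --------------------------------------------------------------------------

def separation_probability(n: int, params: Params) -> float:
    """Probability that an aligned segment of ``n`` base pairs leaves its
    template this step: P_SP ** sqrt(n).  Strictly decreasing in n for
    P_SP < 1; the square root credits single-strand self-folding with
    aiding dissociation."""
    if n < 1:
        raise ValueError("paired length must be >= 1")
    return params.P_SP ** math.sqrt(n)


def bond_break_probability(region: str, outside_protocell: bool,
                           params: Params) -> float:
    """Per-step breaking probability of one backbone position.

    Single-strand regions break with P_BB; in a double-strand region the
    two parallel bonds must break simultaneously (squared probability).
    Outside protocells the single-bond rate is scaled by F_DO first.
    """
    base = params.P_BB * (params.F_DO if outside_protocell else 1.0)
    base = min(1.0, base)
    if region == "single":
        return base
    if region == "double":
        return min(1.0, base * base)
    raise ValueError(f"unknown region {region!r}")


def scan_motifs(sequence: str, seq_defs: SequenceDefs) -> Set[str]:
    """Functional labels carried by a sense strand (exact substring match;
    one substitution in a motif loses the function)."""
    labels = set()
    for label, motif in seq_defs.all_motifs().items():
        if motif in sequence:
            labels.add(label)
    return labels


def strand_labels(strand: RNAStrand, seq_defs: SequenceDefs):
    """Cached ``scan_motifs`` of a strand's template sequence."""
    if strand._labels is None:
        strand._labels = frozenset(scan_motifs(strand.seq, seq_defs))
    return strand._labels


# --------------------------------------------------------------------------
# Small exact samplers
# --------------------------------------------------------------------------

def _binom_inv(u: float, n: int, p: float) -> int:
    """Exact Binomial(n, p) sample by CDF inversion of one uniform."""
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    pmf = (1.0 - p) ** n
    if u < pmf:
        return 0
    cdf = pmf
    k = 0
    ratio = p / (1.0 - p)
    while cdf <= u and k < n:
        k += 1
        pmf *= (n - k + 1) / k * ratio
        cdf += pmf
    return k


def _sample_without_replacement(world: World, pool: List[int],
                                k: int) -> List[int]:
    picked = []
    pool = list(pool)
    for _ in range(k):
        i = int(world.u() * len(pool))
        picked.append(pool.pop(min(i, len(pool) - 1)))
    return picked


def _paired_runs(segs: List[list]) -> List[list]:
    """Maximal contiguous paired intervals [start, end) from sorted,
    non-overlapping segments (abutting segments merge into one run)."""
    runs: List[list] = []
    for seg in segs:
        off = seg[0]
        end = off + len(seg[1])
        if runs and off <= runs[-1][1]:
            runs[-1][1] = end
        else:
            runs.append([off, end])
    return runs


# --------------------------------------------------------------------------
# Degradation
# --------------------------------------------------------------------------

def _binom_inv_pos(u: float, n: int, p: float) -> int:
    """Binomial(n, p) conditioned on being >= 1, by CDF inversion."""
    if p >= 1.0:
        return n
    q = (1.0 - p) ** n
    target = q + u * (1.0 - q)
    pmf = q
    cdf = q
    k = 0
    ratio = p / (1.0 - p)
    while cdf <= target and k < n:
        k += 1
        pmf *= (n - k + 1) / k * ratio
        cdf += pmf
    return max(k, 1)


def degrade_rna(strand: RNAStrand, world: World, r: int, c: int,
                outside: bool) -> List[RNAStrand]:
    """Apply end decay and bond breaking to one unfolded strand.

    All events are decided against the start-of-step strand (unpaired
    terminal residues may decay to precursors; single-strand bonds break
    with the single rate, paired-run bonds with the squared rate) and then
    applied together.  Returns the surviving fragments (possibly empty);
    free nucleotides and precursors produced are credited to the room.
    Folded strands must not be passed here (they are protected).
    """
    p = world.params
    pnde = min(1.0, p.P_NDE * (p.F_DO if outside else 1.0))
    segs = strand.segs
    runs = _paired_runs(segs)
    L = len(strand.seq)
    head_free = not runs or runs[0][0] > 0
    tail_free = not runs or runs[-1][1] < L
    n_free = (1 if head_free else 0) + (1 if tail_free else 0)
    # one end-decay trial per chain per step, hitting a random free end
    k_e = 1 if (n_free and pnde > 0 and world.u() < pnde) else 0

    p_single = bond_break_probability("single", outside, p)
    n_double = sum(e - s - 1 for s, e in runs)
    n_single = (L - 1) - n_double
    k_s = _binom_inv(world.u(), n_single, p_single)
    if n_double:
        p_double = bond_break_probability("double", outside, p)
        k_d = _binom_inv(world.u(), n_double, p_double)
    else:
        k_d = 0
    if not (k_e or k_s or k_d):
        return [strand]
    return _apply_degradation(strand, world, r, c, k_e, k_s, k_d,
                              head_free, tail_free, runs)


def _apply_degradation(strand: RNAStrand, world: World, r: int, c: int,
                       k_e: int, k_s: int, k_d: int, head_free: bool,
                       tail_free: bool, runs: List[list]) -> List[RNAStrand]:
    seq = strand.seq
    L = len(seq)
    n_free = (1 if head_free else 0) + (1 if tail_free else 0)
    lo, hi = 0, L
    if k_e:
        if k_e == n_free:
            decay_head, decay_tail = head_free, tail_free
        else:  # exactly one of two free ends, chosen fairly
            decay_head = world.u() < 0.5
            decay_tail = not decay_head
        if decay_head:
            lo += 1
            world.npre[r, c] += 1
        if decay_tail and hi - lo >= 1:
            hi -= 1
            world.npre[r, c] += 1
    if hi - lo == 0:
        return []

    cuts: List[int] = []
    if k_s or k_d:
        if k_d:
            double_bonds = [j for s, e in runs for j in range(s, e - 1)]
            cut_d = _sample_without_replacement(world, double_bonds, k_d)
        else:
            double_bonds = []
            cut_d = []
        if k_s:
            if double_bonds:
                dset = set(double_bonds)
                single_bonds = [j for j in range(L - 1) if j not in dset]
            else:
                single_bonds = range(L - 1)
            cut_s = _sample_without_replacement(world, single_bonds, k_s)
        else:
            cut_s = []
        cuts = sorted(j + 1 for j in cut_s + cut_d if lo < j + 1 < hi)

    if not cuts:
        if lo == 0 and hi == L:
            return [strand]
        seq2 = seq[lo:hi]
        segs2 = [[seg[0] - lo, seg[1], seg[2]]
                 for seg in strand.segs]  # ends were unpaired
        if len(seq2) == 1:
            world.nt[r, c, BASE_INDEX[seq2]] += 1
            for seg in segs2:  # 1-bp duplex: partner freed as well
                world.nt[r, c, BASE_INDEX[seg[1]]] += 1
            return []
        return [RNAStrand(seq2, segs2)]

    fragments: List[RNAStrand] = []
    starts = [lo] + cuts
    ends = cuts + [hi]
    for a, b in zip(starts, ends):
        piece = seq[a:b]
        piece_segs = []
        for seg in strand.segs:
            t = seg[1]
            s0, s1 = seg[0], seg[0] + len(t)
            o0, o1 = max(s0, a), min(s1, b)
            if o0 < o1:  # a cut inside a paired run severs both strands
                piece_segs.append([o0 - a, t[o0 - s0:o1 - s0], seg[2]])
        if len(piece) == 1:
            world.nt[r, c, BASE_INDEX[piece]] += 1
            for seg in piece_segs:  # 1-bp duplex: partner freed as well
                world.nt[r, c, BASE_INDEX[seg[1]]] += 1
        else:
            fragments.append(RNAStrand(piece, piece_segs))
    return fragments


def _degrade_bare_conditional(strand: RNAStrand, world: World, r: int,
                              c: int, pnde: float, p_single: float,
                              A: float, B: float) -> List[RNAStrand]:
    """Degradation of a complement-free strand given that at least one
    event happens (the no-event case was decided by the caller's gate).

    ``A`` = P(no end decay) = 1-pnde (one trial per chain), ``B`` = P(no
    bond break) = (1-p_single)^(L-1); the joint conditional distribution
    matches ``degrade_rna`` exactly.
    """
    L = len(strand.seq)
    norm = 1.0 - A * B
    p_ke0 = A * (1.0 - B) / norm
    if world.u() < p_ke0:
        k_e = 0
        k_s = _binom_inv_pos(world.u(), L - 1, p_single)
    else:
        k_e = 1
        k_s = _binom_inv(world.u(), L - 1, p_single)
    return _apply_degradation(strand, world, r, c, k_e, k_s, 0,
                              True, True, [])


# --------------------------------------------------------------------------
# Template-directed synthesis
# --------------------------------------------------------------------------

def _release_segment(world: World, r: int, c: int, t: str) -> None:
    """A segment leaving its template becomes a free strand (sequence is
    the reverse of its pairing string) or a free nucleotide."""
    if len(t) == 1:
        world.nt[r, c, BASE_INDEX[t]] += 1
    else:
        world.add_strand(r, c, RNAStrand(t[::-1]))


def separate_segments(strand: RNAStrand, world: World, r: int, c: int) -> None:
    """Separation of aligned material with P_SP ** sqrt(n).

    Only a still-unligated recruited substrate or the full complementary
    chain (a segment spanning the whole template) may leave; a nascent
    ligation product shorter than the template stays attached.
    """
    if not strand.segs:
        return
    p_sp = world.params.P_SP
    L = len(strand.seq)
    keep = []
    for seg in strand.segs:
        t = seg[1]
        n = len(t)
        if (seg[2] or (seg[0] == 0 and n == L)) \
                and world.u() < p_sp ** math.sqrt(n):
            _release_segment(world, r, c, t)
        else:
            keep.append(seg)
    strand.segs = keep


def template_ligation(strand: RNAStrand, params: Params, world=None) -> None:
    """Close each junction between abutting aligned segments with P_TL."""
    if len(strand.segs) < 2:
        return
    draw = world.u if world is not None else np.random.default_rng().random
    merged = [strand.segs[0]]
    for seg in strand.segs[1:]:
        prev = merged[-1]
        if prev[0] + len(prev[1]) == seg[0] and draw() < params.P_TL:
            prev[1] = prev[1] + seg[1]
            prev[2] = False  # a ligated stretch is a nascent chain
        else:
            merged.append(seg)
    strand.segs = merged


def _growth_positions(strand: RNAStrand) -> List[int]:
    """Template positions where the complement may grow: unpaired positions
    adjacent to an existing paired run, or every position if bare."""
    L = len(strand.seq)
    if not strand.segs:
        return list(range(L))
    runs = _paired_runs(strand.segs)
    cand: List[int] = []
    for s, e in runs:
        if s - 1 >= 0 and (s - 1) not in cand:
            cand.append(s - 1)
        if e < L and e not in cand:
            cand.append(e)
    # drop positions that actually sit inside another run (abutting runs
    # are merged, so this only removes duplicates between adjacent runs)
    out = []
    for pos in cand:
        inside = any(s <= pos < e for s, e in runs)
        if not inside:
            out.append(pos)
    return out


def _insert_seg(strand: RNAStrand, off: int, t: str) -> None:
    strand.segs.append([off, t, True])  # a freshly recruited substrate
    strand.segs.sort(key=lambda s: s[0])


def _recruit_monomer(strand: RNAStrand, world: World, nt_counts,
                     pos: int) -> bool:
    """Place one free nucleotide at template position ``pos``: the
    Watson-Crick partner is demanded; with P_FP a mismatching base is
    accepted instead (weighted by availability)."""
    want = _WC_INDEX[BASE_INDEX[strand.seq[pos]]]
    if world.u() >= world.params.P_FP:
        if nt_counts[want] == 0:
            return False
        base_idx = want
    else:
        others = [i for i in range(4) if i != want and nt_counts[i] > 0]
        if not others:
            return False
        weights = [int(nt_counts[i]) for i in others]
        x = world.u() * sum(weights)
        acc = 0
        base_idx = others[-1]
        for i, wgt in zip(others, weights):
            acc += wgt
            if x < acc:
                base_idx = i
                break
    nt_counts[base_idx] -= 1
    _insert_seg(strand, pos, BASES[base_idx])
    return True


def _recruit_oligomer(strand: RNAStrand, world: World, r: int, c: int,
                      pos: int, substrates: Optional[List[RNAStrand]],
                      scan_cap: int = 8) -> bool:
    """Recruit a free complement-less strand whose every base pairs over a
    span through ``pos`` (encounter-limited: up to ``scan_cap`` candidates
    are inspected).  Mismatching oligomers are not pursued - their joint
    acceptance probability P_FP**k is negligible against the monomer
    mutation channel."""
    if not substrates:
        return False
    seq = strand.seq
    L = len(seq)
    runs = _paired_runs(strand.segs) if strand.segs else ()
    n_sub = len(substrates)
    start0 = int(world.u() * n_sub)
    for j in range(min(n_sub, scan_cap)):
        sub = substrates[(start0 + j) % n_sub]
        if sub is strand or sub.bound or sub.segs:
            continue
        sseq = sub.seq
        Ls = len(sseq)
        for st in (pos, pos - Ls + 1):
            if st < 0 or st + Ls > L:
                continue
            if runs and any(s0 < st + Ls and st < e0 for s0, e0 in runs):
                continue
            key = (seq, sseq, st)
            k_mm = _MISMATCH_CACHE.get(key)
            if k_mm is None:
                k_mm = 0
                for k in range(Ls):
                    if BASE_INDEX[sseq[Ls - 1 - k]] != \
                            _WC_INDEX[BASE_INDEX[seq[st + k]]]:
                        k_mm += 1
                if len(_MISMATCH_CACHE) > 200_000:
                    _MISMATCH_CACHE.clear()
                _MISMATCH_CACHE[key] = k_mm
            if k_mm == 0:
                world.remove_strand(r, c, sub)
                substrates.remove(sub)
                _insert_seg(strand, st, sseq[::-1])
                return True
    return False


def attract_substrate(strand: RNAStrand, world: World, r: int, c: int,
                      substrates: Optional[List[RNAStrand]] = None) -> int:
    """Template-side substrate attraction for one step.

    Attraction is base-pairing driven: each growth position of the
    complement (a bare template of at least L_TMPL nucleotides nucleates
    at one uniformly chosen position) recruits a substrate with
    probability P_AT.  A free nucleotide is demanded as the Watson-Crick
    partner, with P_FP a mismatching base accepted instead (mutation);
    when no fitting monomer is free, a fully pairing oligomer from the
    room's free pool is recruited into the nascent chain instead
    (fragment recycling).  Returns the number recruited.
    """
    p = world.params
    nt_counts = world.nt[r, c]
    if not strand.segs:
        if len(strand.seq) < p.L_TMPL:
            return 0  # too short to nucleate a stable complement
        if world.u() >= p.P_AT:
            return 0
        pos = int(world.u() * len(strand.seq))
        if _recruit_monomer(strand, world, nt_counts, pos):
            return 1
        return 1 if _recruit_oligomer(strand, world, r, c, pos,
                                      substrates) else 0
    n = 0
    for pos in _growth_positions(strand):
        if world.u() < p.P_AT:
            if _recruit_monomer(strand, world, nt_counts, pos):
                n += 1
            elif _recruit_oligomer(strand, world, r, c, pos, substrates):
                n += 1
    return n


# --------------------------------------------------------------------------
# Random ligation
# --------------------------------------------------------------------------

def random_ligation(world: World, r: int, c: int) -> None:
    """End-joining of free nucleotides and unfolded RNA chain ends.

    Each unordered pair of candidate ends is considered at most once per
    step with probability P_RL; the event count is drawn as one binomial
    over the pair count and events are realized on uniformly sampled pairs
    (strand-strand joins must be 3'-to-5' compatible; incompatible samples
    are discarded).
    """
    p = world.params
    if p.P_RL <= 0:
        return
    nt_counts = world.nt[r, c]
    n_mono = int(nt_counts[0] + nt_counts[1] + nt_counts[2] + nt_counts[3])
    strands = [s for s in world.room_strands(r, c) if not s.bound]
    ends = n_mono + 2 * len(strands)
    n_pairs = ends * (ends - 1) // 2
    if n_pairs == 0:
        return
    n_events = _binom_inv(world.u(), n_pairs, min(1.0, p.P_RL))
    rng = world.rng
    for _ in range(n_events):
        nt_counts = world.nt[r, c]
        n_mono = int(nt_counts.sum())
        strands = [s for s in world.room_strands(r, c) if not s.bound]
        ends = n_mono + 2 * len(strands)
        if ends < 2:
            return
        e1, e2 = rng.choice(ends, size=2, replace=False)
        _ligate_ends(world, r, c, int(e1), int(e2), n_mono, strands)


def _draw_free_base(world: World, r: int, c: int) -> Optional[str]:
    counts = world.nt[r, c]
    total = int(counts.sum())
    if total == 0:
        return None
    x = world.u() * total
    acc = 0
    for i in range(4):
        acc += int(counts[i])
        if x < acc:
            counts[i] -= 1
            return BASES[i]
    return None  # pragma: no cover


def _ligate_ends(world: World, r: int, c: int, e1: int, e2: int,
                 n_mono: int, strands: List[RNAStrand]) -> None:
    def kind(e):
        if e < n_mono:
            return ("nt", None, None)
        s = strands[(e - n_mono) // 2]
        return ("strand", s, "head" if (e - n_mono) % 2 == 0 else "tail")

    k1, s1, end1 = kind(e1)
    k2, s2, end2 = kind(e2)
    if k1 == "nt" and k2 == "nt":
        b1 = _draw_free_base(world, r, c)
        b2 = _draw_free_base(world, r, c)
        if b1 is None or b2 is None:
            if b1 is not None:
                world.nt[r, c, BASE_INDEX[b1]] += 1
            return
        world.add_strand(r, c, RNAStrand(b1 + b2))
        return
    if k1 == "nt" or k2 == "nt":
        s, end = (s2, end2) if k1 == "nt" else (s1, end1)
        b = _draw_free_base(world, r, c)
        if b is None:
            return
        if end == "head":
            s.seq = b + s.seq
            s.segs = [[seg[0] + 1, seg[1], seg[2]] for seg in s.segs]
        else:
            s.seq = s.seq + b
        s.invalidate()
        return
    if s1 is s2:
        return  # no circularization
    # strand-strand: only tail-to-head joins are chemically compatible
    if end1 == "tail" and end2 == "head":
        first, second = s1, s2
    elif end2 == "tail" and end1 == "head":
        first, second = s2, s1
    else:
        return
    shift = len(first.seq)
    first.seq = first.seq + second.seq
    first.segs = first.segs + [[seg[0] + shift, seg[1], seg[2]]
                               for seg in second.segs]
    first.invalidate()
    world.remove_strand(r, c, second)


# --------------------------------------------------------------------------
# Per-room polymer phase
# --------------------------------------------------------------------------

def step_rna_room(world: World, r: int, c: int) -> None:
    """Degradation -> random ligation -> attraction -> template ligation ->
    separation, each entity at most once per sub-phase."""
    outside = (r, c) not in world.cells
    lst = world.room_strands(r, c)
    if lst:
        # degradation events are independent across strands, so iteration
        # order is immaterial here; a per-length no-event gate decides most
        # strands with a single uniform.
        p = world.params
        pnde = min(1.0, p.P_NDE * (p.F_DO if outside else 1.0))
        p_single = bond_break_probability("single", outside, p)
        A = 1.0 - pnde
        qno: dict = {}
        survivors: List[RNAStrand] = []
        for s in lst:
            if s.bound:
                survivors.append(s)
                continue
            if not s.segs:
                L = len(s.seq)
                entry = qno.get(L)
                if entry is None:
                    B = (1.0 - p_single) ** (L - 1)
                    entry = qno[L] = (A * B, B)
                if world.u() < entry[0]:
                    survivors.append(s)
                else:
                    survivors.extend(_degrade_bare_conditional(
                        s, world, r, c, pnde, p_single, A, entry[1]))
            else:
                survivors.extend(degrade_rna(s, world, r, c, outside))
        if survivors:
            world.strands[(r, c)] = survivors
        else:
            world.strands.pop((r, c), None)

    random_ligation(world, r, c)

    lst = world.room_strands(r, c)
    if lst:
        # template-side substrate recruitment (monomers, or fully pairing
        # oligomers when the fitting monomer is unavailable)
        if len(lst) > 1:
            order = world.rng.permutation(len(lst))
        else:
            order = (0,)
        snapshot = list(lst)
        substrates = [s for s in lst if not s.bound and not s.segs]
        consumed_ids: set = set()
        for i in order:
            s = snapshot[i]
            if s.bound or id(s) in consumed_ids:
                continue
            before = len(substrates)
            had_no_segs = not s.segs
            attract_substrate(s, world, r, c, substrates)
            if len(substrates) != before:
                consumed_ids = {id(x) for x in snapshot} - \
                    {id(x) for x in world.room_strands(r, c)}
            if had_no_segs and s.segs and s in substrates:
                substrates.remove(s)
        # on-template ligation and separation (folding blocks attraction,
        # degradation and random ligation, but aligned material still
        # ligates and duplexes still melt)
        for s in list(world.room_strands(r, c)):
            if s.segs:
                template_ligation(s, world.params, world)
                separate_segments(s, world, r, c)
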