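"""RNA polymer events: degradation, replication machinery and motif
recognition."""

import math

import numpy as np
import pytest

from drtworld.config import BASES, Params, WC, reverse_complement
from drtworld.fixtures import tiny_world, _settle_ledger
from drtworld.rna import (
    attract_substrate, degrade_rna, random_ligation, scan_motifs,
    separate_segments, step_rna_room, template_ligation,
)
from drtworld.world import RNAStrand


def _world(params=None, seed=0):
    return tiny_world("one_room_monomers", seed=seed,
                      params=params or Params(N=1))


# -- degradation ------------------------------------------------------------

def test_degradation_disabled_leaves_strand_untouched():
    w = _world(Params(N=1, P_BB=0, P_NDE=0))
    s = RNAStrand("ACGUACGUAC")
    frags = degrade_rna(s, w, 0, 0, outside=False)
    assert frags == [s]


def test_end_decay_converts_one_residue_to_precursor():
    w = _world(Params(N=1, P_BB=0, P_NDE=1.0))
    s = RNAStrand("ACGUA")
    (frag,) = degrade_rna(s, w, 0, 0, outside=False)
    assert len(frag.seq) == 4
    assert int(w.npre.sum()) == 1


def test_degradation_conserves_residues_under_fuzz():
    rng = np.random.default_rng(11)
    params = Params(N=1, P_BB=0.05, P_NDE=0.05)
    defs = None
    for trial in range(3000):
        w = tiny_world("one_room_monomers", seed=trial,
                       params=params)
        L = int(rng.integers(2, 12))
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=L))
        segs = []
        pos = 0
        while pos < L:
            if rng.random() < 0.4:
                sl = int(rng.integers(1, L - pos + 1))
                segs.append([pos, "".join(WC[b] for b in seq[pos:pos + sl]),
                             bool(rng.integers(2))])
                pos += sl + 1
            else:
                pos += 1
        s = RNAStrand(seq, [list(x) for x in segs])
        before = s.residues
        frags = degrade_rna(s, w, 0, 0, outside=bool(rng.integers(2)))
        after = sum(f.residues for f in frags) \
            + int(w.nt.sum()) + int(w.npre.sum())
        assert before == after, (seq, segs)


def test_mean_break_count_matches_linearity_oracle():
    """A naked 10-mer outside protocells breaks each of its 9 bonds with
    P_BB*F_DO per step; the mean break count over replicates matches."""
    params = Params(N=1, P_NDE=0.0, P_BB=1e-3, F_DO=20.0)
    rate = 9 * params.P_BB * params.F_DO
    reps = 4000
    breaks = 0
    w = _world(params)
    for i in range(reps):
        s = RNAStrand("ACGUACGUAC")
        nt_before = int(w.nt.sum())
        frags = degrade_rna(s, w, 0, 0, outside=True)
        # every cut adds one piece; length-1 pieces land in the free pool
        pieces = len(frags) + (int(w.nt.sum()) - nt_before)
        breaks += pieces - 1
    mean = breaks / reps
    sigma = math.sqrt(rate / reps)  # Poisson-ish
    assert abs(mean - rate) < 5 * sigma


# -- template-directed synthesis --------------------------------------------

def test_attraction_disabled_never_recruits():
    w = _world(Params(N=1, P_AT=0.0))
    w.nt[0, 0, :] = 10
    s = RNAStrand("ACGUACGUAC")
    for _ in range(50):
        assert attract_substrate(s, w, 0, 0) == 0
    assert not s.segs


def test_perfect_fidelity_recruits_watson_crick_partner():
    w = _world(Params(N=1, P_AT=1.0, P_FP=0.0))
    w.nt[0, 0, :] = 100
    s = RNAStrand("GGGGGGGGGG")
    attract_substrate(s, w, 0, 0)
    assert len(s.segs) == 1
    assert s.segs[0][1] == "C"  # complement of G
    assert int(w.nt[0, 0].sum()) == 399


def test_nucleation_requires_minimum_template_length():
    w = _world(Params(N=1, P_AT=1.0, L_TMPL=10))
    w.nt[0, 0, :] = 100
    short = RNAStrand("ACGUA")
    assert attract_substrate(short, w, 0, 0) == 0
    assert not short.segs


def test_template_ligation_certain_and_never():
    s = RNAStrand("ACGUAC", segs=[[0, "UG", True], [2, "CA", True]])
    template_ligation(s, Params(N=1, P_TL=1.0))
    assert len(s.segs) == 1
    assert s.segs[0][1] == "UGCA"
    assert s.segs[0][2] is False  # ligated stretch is a nascent chain
    s2 = RNAStrand("ACGUAC", segs=[[0, "UG", True], [2, "CA", True]])
    template_ligation(s2, Params(N=1, P_TL=0.0))
    assert len(s2.segs) == 2


def test_full_complement_separates_and_reads_reversed():
    w = _world(Params(N=1, P_SP=1.0))
    seq = "ACGUACGUAC"
    comp = "".join(WC[b] for b in seq)
    s = RNAStrand(seq, segs=[[0, comp, False]])
    separate_segments(s, w, 0, 0)
    assert not s.segs
    (released,) = w.room_strands(0, 0)
    assert released.seq == comp[::-1] == reverse_complement(seq)


def test_partial_nascent_chain_cannot_separate():
    w = _world(Params(N=1, P_SP=1.0))
    s = RNAStrand("ACGUACGUAC", segs=[[0, "UGCA", False]])
    separate_segments(s, w, 0, 0)
    assert s.segs  # shorter than the template and already ligated: stays


def test_unligated_substrate_separates_with_base_rate():
    w = _world(Params(N=1, P_SP=1.0))
    s = RNAStrand("ACGUACGUAC", segs=[[3, "A", True]])
    separate_segments(s, w, 0, 0)
    assert not s.segs
    assert int(w.nt.sum()) == 1  # a monomer returns to the free pool


def test_full_copy_cycle_reproduces_template():
    """With deterministic probabilities a template yields an exact copy of
    itself after two rounds of complement synthesis."""
    params = Params(N=1, P_AT=1.0, P_TL=1.0, P_FP=0.0, P_SP=0.5,
                    P_BB=0.0, P_NDE=0.0, P_ND=0.0, P_NF=0.0, P_RL=0.0,
                    P_AABR=0.0)
    w = _world(params, seed=13)
    seq = "ACGUACGUAC"
    w.add_strand(0, 0, RNAStrand(seq))
    w.nt[0, 0, :] = 200
    _settle_ledger(w)
    seen = set()
    copies = 0
    for _ in range(250):
        step_rna_room(w, 0, 0)
        seen |= {s.seq for s in w.room_strands(0, 0)}
        copies = max(copies,
                     sum(1 for s in w.room_strands(0, 0) if s.seq == seq))
    assert reverse_complement(seq) in seen
    assert copies >= 2  # the complement was itself copied back


# -- random ligation ---------------------------------------------------------

def test_random_ligation_disabled():
    w = _world(Params(N=1, P_RL=0.0))
    w.nt[0, 0, 0] = 100
    random_ligation(w, 0, 0)
    assert not w.room_strands(0, 0)


def test_forced_random_ligation_of_two_nucleotides():
    w = _world(Params(N=1, P_RL=1.0))
    w.nt[0, 0, 0] = 2
    random_ligation(w, 0, 0)
    strands = w.room_strands(0, 0)
    assert len(strands) == 1
    assert strands[0].seq == "AA"
    assert int(w.nt.sum()) == 0


def test_random_ligation_count_matches_binomial_oracle():
    """With k nucleotides the number of end pairs is k(k-1)/2; the
    per-step ligation count matches Binomial(pairs, P_RL)."""
    p_rl = 1e-3
    k = 40
    pairs = k * (k - 1) // 2
    reps = 300
    total = 0
    for seed in range(reps):
        w = _world(Params(N=1, P_RL=p_rl), seed=seed)
        w.nt[0, 0, :] = 10
        random_ligation(w, 0, 0)
        total += len(w.room_strands(0, 0))
    mean = total / reps
    expect = pairs * p_rl
    sigma = math.sqrt(pairs * p_rl * (1 - p_rl) / reps)
    assert abs(mean - expect) < 5 * sigma


# -- motif recognition --------------------------------------------------------

def test_motif_identity_and_substring(seq_defs):
    assert scan_motifs(seq_defs.nsr_motif, seq_defs) == {"NSR"}
    embedded = "ACGUA" + seq_defs.mspg_motif + "CCGG"
    assert "MSPG" in scan_motifs(embedded, seq_defs)


def test_single_substitution_destroys_function(seq_defs):
    m = seq_defs.nsr_motif
    for i in range(len(m)):
        for b in BASES:
            if b != m[i]:
                mutated = m[:i] + b + m[i + 1:]
                assert "NSR" not in scan_motifs(mutated, seq_defs)


def test_concatemer_carries_both_labels(seq_defs):
    double = seq_defs.mspg_motif + seq_defs.nsr_motif
    assert scan_motifs(double, seq_defs) == {"MSPG", "NSR"}


def test_complement_of_motif_has_no_function(seq_defs):
    for label in ("MSPG", "NSR", "CTPG"):
        rc = reverse_complement(seq_defs.motif_for(label))
        assert label not in scan_motifs(rc, seq_defs)


def test_replication_fidelity_fraction():
    """The chance that a full 10-mer copy carries at least one mutation is
    1-(1-P_FP)^10; checked against repeated monomer recruitment."""
    p_fp = 0.05
    params = Params(N=1, P_AT=1.0, P_FP=p_fp)
    mutants = 0
    reps = 1500
    seq = "ACGUACGUAC"
    want = reverse_complement(seq)
    for seed in range(reps):
        w = _world(params, seed=seed)
        w.nt[0, 0, :] = 1000
        s = RNAStrand(seq)
        guard = 0
        while sum(len(seg[1]) for seg in s.segs) < 10 and guard < 100:
            attract_substrate(s, w, 0, 0)
            guard += 1
        pairing = "".join(seg[1] for seg in s.segs)
        if pairing[::-1] != want:
            mutants += 1
    frac = mutants / reps
    expect = 1 - (1 - p_fp) ** 10
    sigma = math.sqrt(expect * (1 - expect) / reps)
    assert abs(frac - expect) < 4 * sigma
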