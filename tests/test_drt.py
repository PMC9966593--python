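"""The direct-RNA-template mechanism: binding sites, on-template peptide
synthesis, release, degradation and classification."""

import math

import numpy as np
import pytest

from drtworld.config import AA_INDEX, Params
from drtworld.drt import (
    bind_amino_acid, classify_peptide, degrade_peptides_room,
    drt_ligation, find_binding_sites, release_from_rna, step_drt_room,
)
from drtworld.engine import step
from drtworld.fixtures import tiny_world, _settle_ledger
from drtworld.world import RNAStrand, pair_index


def test_gene_motif_has_two_sites(seq_defs):
    sites = find_binding_sites(seq_defs.mspg_motif, seq_defs)
    assert sites == [(0, seq_defs.msp_pair[0]), (5, seq_defs.msp_pair[1])]


def test_sequence_without_sites(seq_defs):
    assert find_binding_sites(seq_defs.nsr_motif, seq_defs) == []


def test_concatemer_has_four_sites(seq_defs):
    double = seq_defs.mspg_motif + seq_defs.ctpg_motif
    sites = find_binding_sites(double, seq_defs)
    assert [o for o, _ in sites] == [0, 5, 10, 15]


def test_binding_consumes_an_amino_acid(seq_defs):
    w = tiny_world("drt_ready", params=Params(N=1, P_AABR=1.0))
    (s,) = w.room_strands(0, 0)
    site = (0, seq_defs.msp_pair[0])
    before = int(w.aa.sum())
    assert bind_amino_acid(s, site, w, 0, 0)
    assert int(w.aa.sum()) == before - 1
    assert s.folded


def test_binding_never_happens_at_zero_rate(seq_defs):
    w = tiny_world("drt_ready", params=Params(N=1, P_AABR=0.0))
    (s,) = w.room_strands(0, 0)
    for _ in range(100):
        bind_amino_acid(s, (0, seq_defs.msp_pair[0]), w, 0, 0)
    assert not s.bound


def test_binding_rate_matches_published_value(seq_defs):
    w = tiny_world("drt_ready", params=Params(N=1))
    (s,) = w.room_strands(0, 0)
    site = (0, seq_defs.msp_pair[0])
    hits = 0
    reps = 4000
    for _ in range(reps):
        if bind_amino_acid(s, site, w, 0, 0):
            hits += 1
            w.aa[0, 0, AA_INDEX[seq_defs.msp_pair[0]]] += 1
            s.bound.clear()
    sigma = math.sqrt(0.9 * 0.1 / reps)
    assert abs(hits / reps - 0.9) < 4 * sigma


def test_paired_site_cannot_bind(seq_defs):
    w = tiny_world("drt_ready", params=Params(N=1, P_AABR=1.0))
    (s,) = w.room_strands(0, 0)
    from drtworld.config import WC
    s.segs = [[0, "".join(WC[b] for b in s.seq[:5]), False]]
    assert not bind_amino_acid(s, (0, seq_defs.msp_pair[0]), w, 0, 0)


def test_drt_ligation_orders_residues_by_site_order(seq_defs):
    w = tiny_world("drt_ready", params=Params(N=1, P_AATL=1.0))
    (s,) = w.room_strands(0, 0)
    s.bound = {0: seq_defs.msp_pair[0], 5: seq_defs.msp_pair[1]}
    drt_ligation(s, seq_defs, w.params, w)
    assert s.bound == {0: seq_defs.msp_pair}


def test_release_returns_cargo_to_pools(seq_defs):
    w = tiny_world("drt_ready", params=Params(N=1, P_PLR=1.0))
    (s,) = w.room_strands(0, 0)
    s.bound = {0: seq_defs.msp_pair}
    release_from_rna(s, w, 0, 0)
    assert not s.bound and not s.folded
    assert int(w.pep[0, 0, pair_index(seq_defs.msp_pair)]) == 1


def test_forced_chain_yields_one_msp_per_step(seq_defs):
    """bind -> ligate -> release run in sequence inside the polymer
    phase: at unit probabilities the gene releases one MSP every step."""
    p = Params(N=1, P_AABR=1.0, P_AATL=1.0, P_PLR=1.0, P_AAD=0.0,
               P_PBB=0.0, P_AADE=0.0, P_PJM=0.0, P_AT=0.0, P_CB=0.0,
               P_CD=0.0)
    w = tiny_world("drt_ready", params=p)
    idx = pair_index(seq_defs.msp_pair)
    counts = []
    for _ in range(3):
        step(w)
        counts.append(int(w.pep[0, 0, idx]))
    assert counts == [1, 2, 3]



def _unstaged_drt_expected_steps(pab, pli, prel):
    """Absorbing-Markov expectation for the in-step bind -> ligate ->
    release chain, enumerated independently of the implementation."""
    import itertools
    import numpy as np
    from math import comb
    states = ["S0", "S1", "S2", "SD"]  # singles bound / bound dipeptide
    index = {s: i for i, s in enumerate(states)}
    T = np.zeros((4, 4))
    absorb = np.zeros(4)

    def add(dist, state, prob):
        dist[state] = dist.get(state, 0.0) + prob

    for s in range(3):
        dist = {}
        empty = 2 - s
        for k_add in range(empty + 1):
            pb = comb(empty, k_add) * pab ** k_add \
                * (1 - pab) ** (empty - k_add)
            k = s + k_add
            if k == 2:
                # ligation succeeds -> dipeptide, may release immediately
                add(dist, "A", pb * pli * prel)
                add(dist, "SD", pb * pli * (1 - prel))
                # ligation fails -> two singles, each may drop off
                for kept in range(3):
                    pr = comb(2, kept) * (1 - prel) ** kept * prel ** (2 - kept)
                    add(dist, f"S{kept}", pb * (1 - pli) * pr)
            else:
                for kept in range(k + 1):
                    pr = comb(k, kept) * (1 - prel) ** kept * prel ** (k - kept)
                    add(dist, f"S{kept}", pb * pr)
        for state, prob in dist.items():
            if state == "A":
                absorb[s] += prob
            else:
                T[s, index[state]] += prob
    T[3, 3] = 1 - prel
    absorb[3] = prel
    expected = np.linalg.solve(np.eye(4) - T, np.ones(4))
    return expected[0]


def test_drt_throughput_matches_absorbing_markov_oracle(seq_defs):
    """Mean steps to the first released MSP from an empty gene, against an
    independently enumerated absorbing-chain expectation (sites bind,
    adjacent singles ligate and cargo releases within one step; ample
    amino acids)."""
    pab, pli, prel = 0.9, 0.5, 0.2
    expected = _unstaged_drt_expected_steps(pab, pli, prel)

    p = Params(N=1, P_AABR=pab, P_AATL=pli, P_PLR=prel, P_AAD=0.0,
               P_PBB=0.0, P_AADE=0.0, P_PJM=0.0, P_AT=0.0, P_RL=0.0,
               P_CB=0.0, P_CD=0.0, P_BB=0.0, P_NDE=0.0)
    idx = pair_index(seq_defs.msp_pair)
    times = []
    for seed in range(400):
        w = tiny_world("drt_ready", seed=seed, params=p,
                       amino_acids=1000)
        t = 0
        while int(w.pep[0, 0, idx]) == 0:
            step(w)
            t += 1
            assert t < 500
        times.append(t)
    mean = float(np.mean(times))
    se = float(np.std(times)) / math.sqrt(len(times))
    assert abs(mean - expected) < 4 * se + 0.5


def test_lone_single_can_release(seq_defs):
    """In the release stage a lone bound residue returns to the free
    amino-acid pool (the oracle above relies on rebinding being possible)."""
    w = tiny_world("drt_ready", params=Params(N=1, P_PLR=1.0))
    (s,) = w.room_strands(0, 0)
    aa = seq_defs.msp_pair[0]
    s.bound = {0: aa}
    before = int(w.aa[0, 0, AA_INDEX[aa]])
    release_from_rna(s, w, 0, 0)
    assert int(w.aa[0, 0, AA_INDEX[aa]]) == before + 1


def test_classify_is_order_sensitive(seq_defs):
    assert classify_peptide(seq_defs.msp_pair, seq_defs) == "MSP"
    assert classify_peptide(seq_defs.nsp_pair, seq_defs) == "NSP"
    assert classify_peptide(seq_defs.control_pair, seq_defs) == "control"
    reverse = seq_defs.msp_pair[::-1]
    if reverse != seq_defs.msp_pair:
        assert classify_peptide(reverse, seq_defs) == "none"


def test_bond_break_yields_two_amino_acids(seq_defs):
    w = tiny_world("one_room_monomers",
                   params=Params(N=1, P_PBB=1.0, P_AADE=0.0))
    idx = pair_index(seq_defs.msp_pair)
    w.pep[0, 0, idx] = 5
    _settle_ledger(w)
    degrade_peptides_room(w, 0, 0)
    assert int(w.pep.sum()) == 0
    assert int(w.aa.sum()) == 10
    assert int(w.aapre.sum()) == 0


def test_end_decay_yields_amino_acid_plus_precursor(seq_defs):
    w = tiny_world("one_room_monomers",
                   params=Params(N=1, P_PBB=0.0, P_AADE=1.0))
    idx = pair_index(seq_defs.msp_pair)
    w.pep[0, 0, idx] = 4
    _settle_ledger(w)
    degrade_peptides_room(w, 0, 0)
    # P_AADE=1: both ends decay -> two precursors per dipeptide
    assert int(w.pep.sum()) == 0
    assert int(w.aapre.sum()) == 8


def test_folded_rna_is_protected_through_engine_steps(seq_defs):
    """An RNA with bound cargo never loses a nucleotide residue."""
    p = Params(N=1, P_NDE=1.0, P_BB=0.5, P_PLR=0.0, P_AABR=1.0,
               P_AT=0.0, P_CB=0.0, P_CD=0.0)
    w = tiny_world("drt_ready", params=p)
    (s,) = w.room_strands(0, 0)
    s.bound = {0: seq_defs.msp_pair[0]}
    for _ in range(30):
        step(w)
    survivors = w.room_strands(0, 0)
    assert any(x is s and len(x.seq) == 10 for x in survivors)
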