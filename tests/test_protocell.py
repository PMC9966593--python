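"""Membrane assembly/exchange and whole-protocell events."""

import math

import numpy as np
import pytest

from drtworld.config import Params
from drtworld.engine import step
from drtworld.fixtures import tiny_world, _settle_ledger
from drtworld.protocell import (
    break_protocell, divide, exchange_amphiphiles, form_membrane, fuse,
    move_protocell, msp_membrane_exchange, permeate,
)
from drtworld.world import Protocell, RNAStrand, audit_conservation, pair_index


def _world_with_cell(params=None, b=400, i=0, p=0, seed=0):
    return tiny_world("single_cell_msp", seed=seed,
                      params=params or Params(N=3), b=b, i=i, p=p)


def test_form_membrane_consumes_all_free_amphiphiles():
    w = tiny_world("one_room_monomers", params=Params(N=1, P_MF=1.0), am=250)
    assert form_membrane(w, 0, 0)
    assert w.cells[(0, 0)].b == 250
    assert int(w.am.sum()) == 0
    for e, o in audit_conservation(w).values():
        assert e == o


def test_form_membrane_impossible_below_threshold():
    w = tiny_world("one_room_monomers", params=Params(N=1, P_MF=1.0), am=199)
    for _ in range(50):
        assert not form_membrane(w, 0, 0)


def test_exchange_conserves_and_respects_zero_rates():
    p = Params(N=3, P_AJM=0.0, P_ALM=0.0)
    w = _world_with_cell(p, b=300)
    w.am_out[1, 1] = 50
    cell = w.cells[(1, 1)]
    for _ in range(20):
        exchange_amphiphiles(w, 1, 1, cell)
    assert cell.b == 300
    assert int(w.am_out[1, 1]) == 50


def test_msp_membrane_stationary_fraction():
    """A fixed MSP pool cycling between membrane and interior settles at
    the two-state stationary fraction P_PJM/(P_PJM+P_PLM) = 0.9."""
    p = Params(N=3, P_PBB=0.0, P_AADE=0.0)
    w = _world_with_cell(p, b=400)
    defs = w.seq_defs
    idx = pair_index(defs.msp_pair)
    n = 2000
    w.pep[1, 1, idx] = n
    _settle_ledger(w)
    cell = w.cells[(1, 1)]
    samples = []
    for t in range(200):
        msp_membrane_exchange(w, 1, 1, cell)
        if t >= 50:
            samples.append(cell.p)
    frac = np.mean(samples) / n
    q = p.P_PJM / (p.P_PJM + p.P_PLM)
    assert abs(frac - q) < 4 * math.sqrt(q * (1 - q) / n)


def test_non_msp_dipeptide_never_joins_membrane(seq_defs):
    w = _world_with_cell(b=400)
    idx = pair_index(seq_defs.control_pair)
    w.pep[1, 1, idx] = 100
    _settle_ledger(w)
    cell = w.cells[(1, 1)]
    for _ in range(50):
        msp_membrane_exchange(w, 1, 1, cell)
    assert cell.p == 0
    assert int(w.pep[1, 1, idx]) == 100


def test_impermeable_species_never_cross():
    """Free nucleotides, amino acids and peptides inside a protocell stay
    inside across engine steps (only precursors permeate)."""
    p = Params(N=3, P_CB=0.0, P_CD=0.0, P_MC=0.0, P_CF=0.0, P_ND=0.0,
               P_AAD=0.0, P_PBB=0.0, P_AADE=0.0, P_RL=0.0, P_AT=0.0,
               P_PJM=0.0, P_NF=0.0, P_AAF=0.0, P_AABR=0.0)
    w = _world_with_cell(p, b=400)
    w.nt[1, 1, 2] = 50
    w.aa[1, 1, 3] = 40
    w.pep[1, 1, 7] = 30
    _settle_ledger(w)
    for _ in range(40):
        step(w)
    assert int(w.nt[1, 1].sum()) == 50
    assert int(w.nt.sum()) == 50
    assert int(w.aa.sum()) == int(w.aa[1, 1].sum()) == 40
    assert int(w.pep.sum()) == int(w.pep[1, 1].sum()) == 30


def test_precursor_influx_matches_binomial_oracle():
    """Inward permeation from one neighbouring room: each precursor
    crosses with perm/4 per step."""
    from drtworld.protocell import permeation_probability
    p = Params(N=3, P_MV=0.0, P_AF=0.0, P_AD=0.0, P_APP=0.3)
    reps, n0 = 400, 50
    total = 0
    for seed in range(reps):
        w = _world_with_cell(p, b=300, seed=seed)
        w.apre[0, 1] = n0
        _settle_ledger(w)
        cell = w.cells[(1, 1)]
        permeate(w, 1, 1, cell)
        total += int(w.apre[1, 1])
    perm = permeation_probability("Ap", 300, 0, p)
    expect = n0 * perm / 4
    sigma = math.sqrt(n0 * (perm / 4) * (1 - perm / 4) / reps)
    assert abs(total / reps - expect) < 4 * sigma


def test_divide_splits_contents_and_conserves():
    p = Params(N=3)
    means = []
    for seed in range(300):
        w = _world_with_cell(p, b=800, seed=seed)
        w.npre[1, 1] = 100
        for _ in range(6):
            w.add_strand(1, 1, RNAStrand("ACGUACGUAC"))
        _settle_ledger(w)
        cell = w.cells[(1, 1)]
        assert divide(w, 1, 1, cell)
        assert len(w.cells) == 2
        daughters = list(w.cells.values())
        assert sum(d.b for d in daughters) == 800
        means.append(daughters[0].b)
        for e, o in audit_conservation(w).values():
            assert e == o
        assert sum(len(v) for v in w.strands.values()) == 6
    mean = np.mean(means)
    assert abs(mean - 400) < 4 * math.sqrt(800 * 0.25 / 300)


def test_divide_cancelled_without_free_neighbor():
    p = Params(N=1)
    w = tiny_world("one_room_monomers", params=p)
    w.cells[(0, 0)] = Protocell(b=800)
    _settle_ledger(w)
    assert not divide(w, 0, 0, w.cells[(0, 0)])
    assert len(w.cells) == 1


def test_gene_free_daughter_probability():
    """With 5 gene copies assorting independently, one daughter ends up
    gene-free with probability 2 * (1/2)^5."""
    p = Params(N=3)
    empty = 0
    reps = 2000
    for seed in range(reps):
        w = _world_with_cell(p, b=800, seed=seed)
        for _ in range(5):
            w.add_strand(1, 1, RNAStrand("ACGUACGUAC"))
        _settle_ledger(w)
        divide(w, 1, 1, w.cells[(1, 1)])
        counts = [len(w.room_strands(*room)) for room in w.cells]
        if 0 in counts:
            empty += 1
    expect = 2 * 0.5 ** 5
    sigma = math.sqrt(expect * (1 - expect) / reps)
    assert abs(empty / reps - expect) < 4 * sigma


def test_fuse_is_additive():
    p = Params(N=3)
    w = _world_with_cell(p, b=300, p=4)
    w.cells[(1, 2)] = Protocell(b=200, p=1)
    w.npre[1, 2] = 10
    w.add_strand(1, 2, RNAStrand("ACGU"))
    _settle_ledger(w)
    fuse(w, (1, 1), (1, 2))
    assert len(w.cells) == 1
    cell = w.cells[(1, 1)]
    assert cell.b == 500 and cell.p == 5
    assert int(w.npre[1, 1]) == 10
    assert len(w.room_strands(1, 1)) == 1
    for e, o in audit_conservation(w).values():
        assert e == o


def test_break_frees_membrane_components(seq_defs):
    w = _world_with_cell(b=350, p=7)
    break_protocell(w, 1, 1)
    assert not w.cells
    assert int(w.am[1, 1]) == 350
    assert int(w.pep[1, 1, pair_index(seq_defs.msp_pair)]) == 7
    for e, o in audit_conservation(w).values():
        assert e == o


def test_move_protocell_swaps_contents():
    p = Params(N=3, P_MC=1.0)
    w = _world_with_cell(p, b=300, seed=5)
    w.npre[1, 1] = 25      # interior
    w.npre[0, 1] = 7       # some free molecules elsewhere
    w.npre[2, 1] = 7
    w.npre[1, 0] = 7
    w.npre[1, 2] = 7
    _settle_ledger(w)
    assert move_protocell(w, 1, 1)
    (room,) = w.cells
    assert room != (1, 1)
    assert int(w.npre[room]) == 25        # interior travelled with the cell
    assert int(w.npre[1, 1]) == 7         # displaced molecules swapped back
    for e, o in audit_conservation(w).values():
        assert e == o
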