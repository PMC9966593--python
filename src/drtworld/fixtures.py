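"""Deterministic miniature worlds for event-level testing.

These constructors bypass ``init_world``'s random scatter so tests can
assert exact event outcomes in milliseconds; they are seed-deterministic
and ledger-consistent.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import Params, SequenceDefs, default_sequence_defs
from .world import Protocell, RNAStrand, World, pair_index


def _blank(params: Params, seq_defs: Optional[SequenceDefs], seed) -> World:
    if seq_defs is None:
        seq_defs = default_sequence_defs(0)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return World(params, seq_defs, rng)


def tiny_world(case: str, seed: int = 0, *, params: Optional[Params] = None,
               seq_defs: Optional[SequenceDefs] = None, **kw) -> World:
    """Named micro-fixtures.

    - ``one_room_monomers``: N=1, only counts (``npre``, ``nt``, ... kw).
    - ``single_cell_msp``: one protocell with configurable b, i, p (i is
      realized as free nucleotides inside).
    - ``duplex``: one template with a full-length complement of ``n``
      paired bases (template length ``n``).
    - ``drt_ready``: one protocell holding an MSPG copy and ample amino
      acids of the two MSP residue types.
    - ``competition_micro``: N=5 with one NSR protocell and one NSPG
      protocell plus nucleotide precursors everywhere.
    """
    if case == "one_room_monomers":
        p = (params or Params()).replace(N=1)
        w = _blank(p, seq_defs, seed)
        for name in ("npre", "apre", "aapre", "am"):
            if name in kw:
                getattr(w, name)[0, 0] = kw[name]
        if "nt" in kw:
            w.nt[0, 0, 0] = kw["nt"]
        if "aa" in kw:
            w.aa[0, 0, 0] = kw["aa"]
        _settle_ledger(w)
        return w

    if case == "single_cell_msp":
        p = (params or Params()).replace(N=3)
        w = _blank(p, seq_defs, seed)
        b = kw.get("b", 2 * p.L_AM)
        i = kw.get("i", 0)
        p_msp = kw.get("p", 0)
        w.cells[(1, 1)] = Protocell(b=b, p=p_msp)
        w.nt[1, 1, 0] = i
        _settle_ledger(w)
        return w

    if case == "duplex":
        p = (params or Params()).replace(N=1)
        w = _blank(p, seq_defs, seed)
        n = kw.get("n", 4)
        rng = np.random.default_rng(seed)
        from .config import BASES, WC
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=max(n, 2)))
        comp = "".join(WC[b] for b in seq[:n])
        w.add_strand(0, 0, RNAStrand(seq, segs=[[0, comp, True]]))
        _settle_ledger(w)
        return w

    if case == "drt_ready":
        p = params or Params()
        w = _blank(p.replace(N=1), seq_defs, seed)
        defs = w.seq_defs
        w.cells[(0, 0)] = Protocell(b=2 * p.L_AM)
        w.add_strand(0, 0, RNAStrand(defs.mspg_motif))
        from .config import AA_INDEX
        amount = kw.get("amino_acids", 100)
        w.aa[0, 0, AA_INDEX[defs.msp_pair[0]]] = amount
        w.aa[0, 0, AA_INDEX[defs.msp_pair[1]]] = amount
        _settle_ledger(w)
        return w

    if case == "competition_micro":
        p = (params or Params()).replace(N=5)
        w = _blank(p, seq_defs, seed)
        defs = w.seq_defs
        w.cells[(1, 1)] = Protocell(b=2 * p.L_AM)
        w.add_strand(1, 1, RNAStrand(defs.nsr_motif))
        w.cells[(3, 3)] = Protocell(b=2 * p.L_AM)
        w.add_strand(3, 3, RNAStrand(defs.nspg_motif))
        w.npre += kw.get("npre_per_room", 20)
        w.aapre += kw.get("aapre_per_room", 20)
        _settle_ledger(w)
        return w

    raise ValueError(f"unknown fixture case {case!r}")


def _settle_ledger(world: World) -> None:
    totals = world.observed_totals()
    world.ledger.nucleotide = totals["nucleotide"]
    world.ledger.amphiphile = totals["amphiphile"]
    world.ledger.amino_acid = totals["amino_acid"]
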