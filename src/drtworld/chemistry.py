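"""Monomer chemistry: formation of nucleotides, amphiphiles and amino acids
from their precursors, the reverse decay, and catalysis of nucleotide
formation by the nucleotide synthetase ribozyme (NSR) or peptide (NSP).

All events are i.i.d. Bernoulli per molecule per step, so they are batched
room-wise as binomial draws (statistically identical; the equivalence is
asserted by test).  Formation and decay within one step act on the counts
as they stood at the start of the phase, so no molecule is converted twice
in one step.
"""

from __future__ import annotations

import numpy as np

from .config import Params
from .world import World, pair_index


def nucleotide_formation_probability(catalyst: str, params: Params) -> float:
    """Per-precursor nucleotide formation probability given the catalyst
    present in the room: none -> P_NF, NSR -> P_NFR, NSP -> P_NFP, both ->
    the better of the two (catalysts are alternatives, not additive)."""
    if catalyst == "none":
        return params.P_NF
    if catalyst == "NSR":
        return params.P_NFR
    if catalyst == "NSP":
        return params.P_NFP
    if catalyst == "both":
        return max(params.P_NFR, params.P_NFP)
    raise ValueError(f"unknown catalyst {catalyst!r}")


def catalysis_map(world: World) -> np.ndarray:
    """Per-room nucleotide-formation probability after the catalysis
    lookup.  One functional catalyst upgrades the whole room for the step;
    copies do not stack."""
    from .rna import strand_labels

    p = np.full((world.N, world.N), world.params.P_NF)
    nsp_idx = pair_index(world.seq_defs.nsp_pair)
    nsp_rooms = world.pep[:, :, nsp_idx] > 0
    defs = world.seq_defs
    for (r, c), lst in world.strands.items():
        for s in lst:
            labels = s._labels
            if labels is None:
                labels = strand_labels(s, defs)
            if "NSR" in labels:
                has_nsp = nsp_rooms[r, c]
                p[r, c] = nucleotide_formation_probability(
                    "both" if has_nsp else "NSR", world.params)
                break
        else:
            continue
    nsr_rooms = p > world.params.P_NF
    only_nsp = nsp_rooms & ~nsr_rooms
    p[only_nsp] = world.params.P_NFP
    return p


def _binom(rng: np.random.Generator, n: np.ndarray, p) -> np.ndarray:
    out = np.zeros_like(n)
    mask = n > 0
    if np.any(mask):
        out[mask] = rng.binomial(n[mask], np.broadcast_to(p, n.shape)[mask])
    return out


def step_monomer_chemistry(world: World) -> None:
    """One chemistry phase over the whole grid (vectorized)."""
    p = world.params
    rng = world.rng
    cell_mask = np.zeros((world.N, world.N), dtype=bool)
    for (r, c) in world.cells:
        cell_mask[r, c] = True

    # ---- formation (from start-of-phase precursor counts) ---------------
    pnf = catalysis_map(world)
    new_nt = _binom(rng, world.npre, pnf)
    new_am = _binom(rng, world.apre, p.P_AF)
    new_aa = _binom(rng, world.aapre, p.P_AAF)

    # ---- decay (from start-of-phase monomer counts) ----------------------
    # nucleotides decay faster outside protocells (F_DO); amphiphiles and
    # amino acids take no F_DO scaling (water-activity factor is a
    # nucleotide/RNA effect in this model).
    pnd = np.where(cell_mask, p.P_ND, min(1.0, p.P_ND * p.F_DO))
    dec_nt = _binom(rng, world.nt, pnd[:, :, None])
    dec_am_in = _binom(rng, world.am, p.P_AD)
    dec_am_out = _binom(rng, world.am_out, p.P_AD)
    dec_aa = _binom(rng, world.aa, p.P_AAD)

    # ---- apply -----------------------------------------------------------
    world.npre += -new_nt + dec_nt.sum(axis=2)
    world.apre += -new_am + dec_am_in + dec_am_out
    world.aapre += -new_aa + dec_aa.sum(axis=2)
    world.nt -= dec_nt
    world.am -= dec_am_in
    world.am_out -= dec_am_out
    world.aa -= dec_aa

    # newly formed monomers pick a type uniformly
    flat_nt = new_nt.ravel()
    nz = np.nonzero(flat_nt)[0]
    if nz.size:
        world.nt.reshape(-1, 4)[nz] += rng.multinomial(
            flat_nt[nz], np.full(4, 0.25))
    world.am += new_am
    flat_aa = new_aa.ravel()
    nz = np.nonzero(flat_aa)[0]
    if nz.size:
        world.aa.reshape(-1, 6)[nz] += rng.multinomial(
            flat_aa[nz], np.full(6, 1 / 6))

    # ---- membrane amphiphile decay (protected by F_DW) -------------------
    p_mem = p.P_AD * p.F_DW
    for (r, c), cell in list(world.cells.items()):
        if cell.b > 0 and p_mem > 0:
            k = world.binom(cell.b, p_mem)
            if k:
                cell.b -= k
                world.apre[r, c] += k  # decay product lands inside the cell
                if cell.b <= 0:
                    _dissolve(world, r, c)


def _dissolve(world: World, r: int, c: int) -> None:
    """Membrane lost its last amphiphile: the protocell ceases to exist and
    its (former) interior becomes naked room content."""
    cell = world.cells.pop((r, c))
    world.am[r, c] += cell.b
    if cell.p:
        world.pep[r, c, pair_index(world.seq_defs.msp_pair)] += cell.p
    world.am[r, c] += world.am_out[r, c]
    world.am_out[r, c] = 0
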