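"""The direct RNA template (DRT) mechanism and peptide degradation.

An RNA carrying characteristic binding-site 5-mers binds free amino acids
of the matching types (P_AABR per site per step); two amino acids on
adjacent sites are ligated into a bound dipeptide (P_AATL); bound cargo is
released with P_PLR (a dipeptide becomes a free peptide, a lone residue
returns to the amino-acid pool).  While anything is bound the RNA is
folded: it neither replicates nor degrades, and the cargo itself is
protected too.  Free dipeptides degrade by peptide-bond breaking (P_PBB ->
two amino acids) or chain-end residue decay (P_AADE -> one amino acid +
one precursor); inside the membrane both rates are damped by F_DW.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import AA_INDEX, AA_TYPES, Params, SequenceDefs
from .world import Protocell, RNAStrand, World, pair_index


def find_binding_sites(sequence: str, seq_defs: SequenceDefs,
                       l_aabs: int = 5) -> List[Tuple[int, str]]:
    """Non-overlapping left-to-right scan for codebook 5-mers.

    Returns (offset, amino-acid type) pairs; a gene motif yields its two
    sites at offsets 0 and 5 relative to the motif start.
    """
    sites = []
    i = 0
    L = len(sequence)
    while i + l_aabs <= L:
        aa = seq_defs.codebook.get(sequence[i:i + l_aabs])
        if aa is not None:
            sites.append((i, aa))
            i += l_aabs
        else:
            i += 1
    return sites


def strand_sites(strand: RNAStrand, seq_defs: SequenceDefs) -> List[Tuple[int, str]]:
    """Cached binding sites of a strand."""
    if strand._sites is None:
        strand._sites = find_binding_sites(strand.seq, seq_defs)
    return strand._sites


def _occupied(strand: RNAStrand, off: int) -> bool:
    if off in strand.bound:
        return True
    prev = strand.bound.get(off - 5)
    return prev is not None and len(prev) == 2


def _site_paired(strand: RNAStrand, off: int, l_aabs: int = 5) -> bool:
    for seg in strand.segs:
        if seg[0] < off + l_aabs and off < seg[0] + len(seg[1]):
            return True
    return False


def bind_amino_acid(strand: RNAStrand, site: Tuple[int, str], world: World,
                    r: int, c: int) -> bool:
    """One binding attempt at an unoccupied site: with P_AABR a free amino
    acid of the site's type leaves the pool and occupies the site.  A site
    overlapped by the growing complement is double-stranded and cannot
    bind."""
    off, aa = site
    if _occupied(strand, off):
        return False
    if strand.segs and _site_paired(strand, off):
        return False
    idx = AA_INDEX[aa]
    if world.aa[r, c, idx] <= 0:
        return False
    if world.u() >= world.params.P_AABR:
        return False
    world.aa[r, c, idx] -= 1
    strand.bound[off] = aa
    return True


def drt_ligation(strand: RNAStrand, seq_defs: SequenceDefs, params: Params,
                 world: Optional[World] = None) -> None:
    """Ligate adjacent single residues into bound dipeptides (P_AATL).
    Residue order follows site order along the template."""
    sites = strand_sites(strand, seq_defs)
    for (o1, _), (o2, _) in zip(sites, sites[1:]):
        if o2 - o1 != 5:
            continue
        a = strand.bound.get(o1)
        b = strand.bound.get(o2)
        if a and b and len(a) == 1 and len(b) == 1:
            draw = world.u() if world is not None else np.random.random()
            if draw < params.P_AATL:
                strand.bound[o1] = a + b
                del strand.bound[o2]


def release_from_rna(strand: RNAStrand, world: World, r: int, c: int) -> None:
    """Each bound entity independently leaves with P_PLR; the strand
    unfolds when nothing remains bound."""
    p = world.params
    for off in list(strand.bound):
        if world.u() < p.P_PLR:
            cargo = strand.bound.pop(off)
            if len(cargo) == 1:
                world.aa[r, c, AA_INDEX[cargo]] += 1
            else:
                world.pep[r, c, pair_index(cargo)] += 1


def classify_peptide(pair: str, seq_defs: SequenceDefs) -> str:
    """MSP | NSP | control | none, by exact ordered residue-pair match."""
    if pair == seq_defs.msp_pair:
        return "MSP"
    if pair == seq_defs.nsp_pair:
        return "NSP"
    if pair == seq_defs.control_pair:
        return "control"
    return "none"


# --------------------------------------------------------------------------
# Peptide degradation
# --------------------------------------------------------------------------

def _degrade_pool(world: World, r: int, c: int, idx: int, n: int,
                  p_bond: float, p_end: float) -> int:
    """Degrade ``n`` identical free dipeptides; returns survivors.

    Bond breaking yields two free amino acids (directly reusable); end
    decay turns one residue into a precursor and frees the other.
    """
    a = idx // len(AA_TYPES)
    b = idx % len(AA_TYPES)
    n_break = world.binom(n, min(1.0, p_bond)) if p_bond > 0 else 0
    if n_break:
        world.aa[r, c, a] += n_break
        world.aa[r, c, b] += n_break
    rest = n - n_break
    if rest == 0 or p_end <= 0:
        return rest
    pe = min(1.0, p_end)
    # per dipeptide the two ends decay independently with pe
    any_decay = world.binom(rest, 1.0 - (1.0 - pe) ** 2)
    none_ = rest - any_decay
    if any_decay:
        # among decayers: both ends with pe^2 / (1-(1-pe)^2), else one end
        p_both = pe * pe / (1.0 - (1.0 - pe) ** 2)
        both = world.binom(any_decay, p_both)
        first = world.binom(any_decay - both, 0.5)
        second = any_decay - both - first
    else:
        both = first = second = 0
    if first:   # first residue decays, second freed
        world.aapre[r, c] += first
        world.aa[r, c, b] += first
    if second:
        world.aapre[r, c] += second
        world.aa[r, c, a] += second
    if both:
        world.aapre[r, c] += 2 * both
    return int(none_)


def degrade_peptides_room(world: World, r: int, c: int) -> None:
    """Free-dipeptide degradation for one room (batched per pair type)."""
    p = world.params
    counts = world.pep[r, c]
    nz = np.nonzero(counts)[0]
    for idx in nz:
        counts[idx] = _degrade_pool(world, r, c, int(idx), int(counts[idx]),
                                    p.P_PBB, p.P_AADE)


def degrade_membrane_msp(world: World, r: int, c: int,
                         cell: Protocell) -> None:
    """Membrane-embedded MSP degrades at F_DW-damped rates; the products
    are released into the cell interior and p decreases."""
    if cell.p <= 0:
        return
    p = world.params
    idx = pair_index(world.seq_defs.msp_pair)
    before = cell.p
    survivors = _degrade_pool(world, r, c, idx, before,
                              p.P_PBB * p.F_DW, p.P_AADE * p.F_DW)
    cell.p = survivors


# --------------------------------------------------------------------------
# Per-room DRT phase
# --------------------------------------------------------------------------

def step_drt_room(world: World, r: int, c: int) -> None:
    """Bind -> ligate -> release in sequence for every strand with
    binding sites (three distinct phase-3 operations, exactly as
    degradation and attraction both act on a strand within the polymer
    phase).  (Free-peptide degradation runs separately over all rooms.)"""
    defs = world.seq_defs
    for strand in list(world.room_strands(r, c)):
        sites = strand._sites
        if sites is None:
            sites = strand_sites(strand, defs)
        if not sites:
            continue
        for site in sites:
            if not _occupied(strand, site[0]) \
                    and not (strand.segs and _site_paired(strand, site[0])):
                bind_amino_acid(strand, site, world, r, c)
        drt_ligation(strand, world.seq_defs, world.params, world)
        if strand.bound:
            release_from_rna(strand, world, r, c)
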