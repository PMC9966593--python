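"""Membrane assembly and exchange, the MSP membrane effect, precursor
permeation, and whole-protocell events (move, divide, fuse, break).

The closed-form kernels follow the model's mean-field arguments: membrane
formation 1-(1-P_MF)^(a-L_AM+1); amphiphile desorption P_ALM/(y*z) with
the osmotic factor y = 1 + i/(b/2)^(3/2) and the peptide factor
z = 1 + F_MSP*p; precursor permeation scaled by membrane size b/L_AM (and
Donnan-suppressed by y's concentration term for the charged nucleotide
precursors); division P_CD*(1 - 2*L_AM/b).
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .config import Params
from .world import Protocell, RNAStrand, World, pair_index


# --------------------------------------------------------------------------
# Probability kernels
# --------------------------------------------------------------------------

def membrane_formation_probability(a: int, params: Params) -> float:
    """0 below the threshold L_AM, else 1 - (1 - P_MF)^(a - L_AM + 1)."""
    if a < 0:
        raise ValueError("amphiphile count must be >= 0")
    if a < params.L_AM:
        return 0.0
    x = a - params.L_AM + 1
    if x == 1:
        return params.P_MF  # exact identity at the threshold
    return 1.0 - (1.0 - params.P_MF) ** x


def amphiphile_leave_probability(b: int, i: int, p: int,
                                 params: Params) -> float:
    """P_ALM / (y * z): desorption is damped by osmotic swelling (y) and by
    membrane-embedded MSP (z)."""
    if b < 2:
        raise ValueError("membrane must hold at least 2 amphiphiles")
    y = 1.0 + i / (b / 2.0) ** 1.5
    z = 1.0 + params.F_MSP * p
    return params.P_ALM / (y * z)


def permeation_probability(species: str, b: int, i: int,
                           params: Params) -> float:
    """Per-precursor membrane crossing probability, capped at 1.

    Nucleotide precursors (charged) are Donnan-suppressed by the inner
    impermeable ions; amphiphile and amino-acid precursors see only the
    membrane-size factor b/L_AM.
    """
    if b < 2:
        raise ValueError("membrane must hold at least 2 amphiphiles")
    scale = b / params.L_AM
    if species == "Np":
        y = 1.0 + i / (b / 2.0) ** 1.5
        return min(1.0, params.P_NPP * scale / y)
    if species == "Ap":
        return min(1.0, params.P_APP * scale)
    if species == "Aap":
        return min(1.0, params.P_AAPP * scale)
    raise ValueError(f"unknown species {species!r}")


def division_probability(b: int, params: Params) -> float:
    """max(0, P_CD * (1 - 2*L_AM/b)): only cells beyond twice the membrane
    threshold can divide."""
    if b < 1:
        raise ValueError("membrane must hold at least 1 amphiphile")
    return max(0.0, params.P_CD * (1.0 - 2.0 * params.L_AM / b))


# --------------------------------------------------------------------------
# Membrane formation and exchange
# --------------------------------------------------------------------------

def form_membrane(world: World, r: int, c: int) -> bool:
    """All free amphiphiles of a cell-free room assemble into a membrane
    with the formation kernel's probability."""
    a = int(world.am[r, c])
    if (r, c) in world.cells:
        return False
    if world.u() < membrane_formation_probability(a, world.params):
        world.cells[(r, c)] = Protocell(b=a)
        world.am[r, c] = 0
        return True
    return False


def exchange_amphiphiles(world: World, r: int, c: int,
                         cell: Protocell, i_ions: Optional[int] = None) -> None:
    """Ambient and interior free amphiphiles join with P_AJM; membrane
    amphiphiles leave into the ambient pool with the desorption kernel."""
    p = world.params
    join_out = world.binom(int(world.am_out[r, c]), p.P_AJM)
    join_in = world.binom(int(world.am[r, c]), p.P_AJM)
    b_eff = max(cell.b, 2)
    if i_ions is None:
        i_ions = world.inner_ions(r, c)
    leave_p = amphiphile_leave_probability(b_eff, i_ions, cell.p, p)
    leave = world.binom(cell.b, leave_p)
    world.am_out[r, c] += leave - join_out
    world.am[r, c] -= join_in
    cell.b += join_out + join_in - leave
    if cell.b <= 0:
        from .chemistry import _dissolve
        _dissolve(world, r, c)


def msp_membrane_exchange(world: World, r: int, c: int,
                          cell: Protocell) -> None:
    """Free MSP inside joins the membrane with P_PJM; embedded MSP leaves
    into the interior with P_PLM.  No other dipeptide can join."""
    p = world.params
    idx = pair_index(world.seq_defs.msp_pair)
    free = int(world.pep[r, c, idx])
    join = world.binom(free, p.P_PJM)
    leave = world.binom(cell.p, p.P_PLM)
    world.pep[r, c, idx] += leave - join
    cell.p += join - leave


# --------------------------------------------------------------------------
# Permeation
# --------------------------------------------------------------------------

_SPECIES_ARRAYS = (("Np", "npre"), ("Ap", "apre"), ("Aap", "aapre"))


def permeate(world: World, r: int, c: int, cell: Protocell,
             i_ions: Optional[int] = None) -> None:
    """Precursor exchange through one cell's membrane.

    Outward: each interior precursor picks one of the four directions and
    crosses with the permeation probability (cancelled off-grid or into
    another protocell).  Inward: each precursor in a cell-free neighbour
    room crosses with probability perm/4 (the 1/4 being the direction
    choice).  The same kernel is used in both directions.
    """
    p = world.params
    if cell.b < 2:
        return
    if i_ions is None:
        i_ions = world.inner_ions(r, c)
    all_nbrs = _dir_targets(world, r, c)
    open_nbrs = [t for t in all_nbrs
                 if t[0] is not None and t not in world.cells]
    for species, attr in _SPECIES_ARRAYS:
        perm = permeation_probability(species, cell.b, i_ions, p)
        if perm <= 0:
            continue
        arr = getattr(world, attr)
        # outward
        n_in = int(arr[r, c])
        if n_in > 0:
            crossers = world.binom(n_in, perm)
            if crossers:
                dirs = world.split4(crossers)
                for k, (rr, cc) in enumerate(all_nbrs):
                    if rr is None or (rr, cc) in world.cells:
                        continue  # reflected or blocked by another membrane
                    moved = dirs[k]
                    if moved:
                        arr[r, c] -= moved
                        arr[rr, cc] += moved
        # inward
        p_in = min(1.0, perm / 4.0)
        for rr, cc in open_nbrs:
            k = world.binom(int(arr[rr, cc]), p_in)
            if k:
                arr[rr, cc] -= k
                arr[r, c] += k


def _dir_targets(world: World, r: int, c: int) -> List[Tuple]:
    out = []
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        rr, cc = r + dr, c + dc
        if world.params.toroidal:
            out.append((rr % world.N, cc % world.N))
        elif 0 <= rr < world.N and 0 <= cc < world.N:
            out.append((rr, cc))
        else:
            out.append((None, None))
    return out


# --------------------------------------------------------------------------
# Whole-cell events
# --------------------------------------------------------------------------

def break_protocell(world: World, r: int, c: int) -> None:
    """Membrane disassembles: b amphiphiles and p MSP are freed in the
    room and the former interior becomes naked content."""
    from .chemistry import _dissolve
    _dissolve(world, r, c)


def _split_array_contents(world: World, src, dst, rng) -> None:
    for attr in ("npre", "apre", "aapre"):
        arr = getattr(world, attr)
        n = int(arr[src])
        if n:
            k = rng.binomial(n, 0.5)
            arr[src] -= k
            arr[dst] += k
    for attr in ("nt", "aa", "pep"):
        arr = getattr(world, attr)
        v = arr[src]
        nz = np.nonzero(v)[0]
        for idx in nz:
            k = rng.binomial(int(v[idx]), 0.5)
            if k:
                arr[src][idx] -= k
                arr[dst][idx] += k
    n = int(world.am[src])
    if n:
        k = rng.binomial(n, 0.5)
        world.am[src] -= k
        world.am[dst] += k


def divide(world: World, r: int, c: int, cell: Protocell) -> bool:
    """Binomial fission into a uniformly chosen adjacent cell-free room.

    Membrane amphiphiles, membrane MSP and every interior entity are
    assigned to either daughter with probability 1/2 ("random
    assortment").  Free molecules previously in the offspring room are
    displaced to a cell-free neighbour of that room (engulfed by the
    offspring if it has none).  Returns False if no eligible room exists.
    """
    rng = world.rng
    options = [(rr, cc) for rr, cc in world.neighbors(r, c)
               if (rr, cc) not in world.cells]
    if not options:
        return False
    dst = options[int(rng.integers(len(options)))]

    # displace the target room's prior free contents
    refuges = [(rr, cc) for rr, cc in world.neighbors(*dst)
               if (rr, cc) not in world.cells and (rr, cc) != (r, c)]
    refuge = refuges[int(rng.integers(len(refuges)))] if refuges else None
    if refuge is not None:
        _move_room_contents(world, dst, refuge)
    # else: contents stay put and are engulfed into the offspring interior

    b1 = int(rng.binomial(cell.b, 0.5))
    b1 = min(max(b1, 1), cell.b - 1) if cell.b >= 2 else b1
    p1 = int(rng.binomial(cell.p, 0.5)) if cell.p else 0
    daughter = Protocell(b=cell.b - b1, p=cell.p - p1)
    cell.b, cell.p = b1, p1

    _split_array_contents(world, (r, c), dst, rng)
    src_strands = world.strands.pop((r, c), [])
    keep, give = [], []
    for s in src_strands:
        (keep if rng.random() < 0.5 else give).append(s)
    if keep:
        world.strands[(r, c)] = keep
    if give:
        world.strands.setdefault(dst, []).extend(give)
    world.cells[dst] = daughter
    return True


def _move_room_contents(world: World, src, dst) -> None:
    """Move every free entity of a cell-free room to another room."""
    for attr in ("npre", "apre", "aapre", "am"):
        arr = getattr(world, attr)
        arr[dst] += arr[src]
        arr[src] = 0
    for attr in ("nt", "aa", "pep"):
        arr = getattr(world, attr)
        arr[dst] += arr[src]
        arr[src] = 0
    moved = world.strands.pop(src, None)
    if moved:
        world.strands.setdefault(dst, []).extend(moved)


def fuse(world: World, room_a, room_b) -> None:
    """Merge the protocell of room_b into room_a (membranes and interiors
    are additive); room_b becomes protocell-free and empty."""
    cell_a = world.cells[room_a]
    cell_b = world.cells.pop(room_b)
    cell_a.b += cell_b.b
    cell_a.p += cell_b.p
    _move_room_contents(world, room_b, room_a)
    # ambient amphiphiles of the vacated room stay there as plain free ones
    world.am[room_b] += world.am_out[room_b]
    world.am_out[room_b] = 0


def move_protocell(world: World, r: int, c: int) -> bool:
    """Relocate the whole protocell to a uniformly chosen adjacent cell-free
    room, swapping that room's free contents into the vacated room."""
    rng = world.rng
    options = [(rr, cc) for rr, cc in world.neighbors(r, c)]
    if not options:
        return False
    dst = options[int(rng.integers(len(options)))]
    if dst in world.cells:
        return False  # fusion is a separate event
    src = (r, c)
    # swap: interior arrays <-> target room free arrays
    for attr in ("npre", "apre", "aapre", "am"):
        arr = getattr(world, attr)
        arr[src], arr[dst] = int(arr[dst]), int(arr[src])
    for attr in ("nt", "aa", "pep"):
        arr = getattr(world, attr)
        tmp = arr[src].copy()
        arr[src] = arr[dst]
        arr[dst] = tmp
    s_src = world.strands.pop(src, None)
    s_dst = world.strands.pop(dst, None)
    if s_dst:
        world.strands[src] = s_dst
    if s_src:
        world.strands[dst] = s_src
    world.cells[dst] = world.cells.pop(src)
    # ambient pools are room properties: the vacated room's ambient merges
    # into its now-free pool; the occupied room's free amphiphiles were
    # swapped to the vacated room already, its ambient starts at the prior
    # ambient value (0 for a previously cell-free room).
    world.am[src] += world.am_out[src]
    world.am_out[src] = 0
    return True
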