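"""The Monte Carlo step loop.

Each step applies five phases in a fixed, documented order (a config flag
can shuffle them for robustness experiments):

1. protocell events - break, divide, fuse, move;
2. membrane/transport - formation, amphiphile exchange, MSP exchange,
   precursor permeation;
3. polymer events - RNA degradation, random ligation, template
   attraction/ligation/separation, DRT binding/ligation/release, peptide
   degradation, membrane-MSP degradation;
4. monomer chemistry - formation (with catalysis lookup) and decay;
5. movement of free entities.

Within a phase entities are visited in randomized order and acted on at
most once.  All randomness flows from the world's single seeded generator,
so identical (seed, params, scenario) triples give bitwise-identical
output streams.
"""

from __future__ import annotations

import math
from typing import List, Optional

import numpy as np
import pandas as pd

from . import chemistry, drt, protocell as pc, rna
from .config import Params, Scenario
from .world import World


def polymer_move_probability(m: float, params: Params) -> float:
    """P_MV / sqrt(m): Zimm-model scaling of polymer diffusion with the
    relative mass m (nucleotide/amino-acid residues of the complex)."""
    if m < 1:
        raise ValueError("relative mass must be >= 1")
    return params.P_MV / math.sqrt(m)


# --------------------------------------------------------------------------
# Phases
# --------------------------------------------------------------------------

def _phase_protocells(world: World) -> None:
    p = world.params
    rng = world.rng
    rooms = list(world.cells)
    if len(rooms) > 1:
        rng.shuffle(rooms)
    acted = set()
    for room in rooms:
        if room in acted or room not in world.cells:
            continue
        cell = world.cells[room]
        r, c = room
        if world.u() < p.P_CB:
            pc.break_protocell(world, r, c)
            acted.add(room)
            continue
        if world.u() < pc.division_probability(max(cell.b, 1), p):
            if pc.divide(world, r, c, cell):
                acted.add(room)
                continue
        fused = False
        for nbr in world.neighbors(r, c):
            if nbr in world.cells and nbr not in acted and nbr != room:
                if world.u() < p.P_CF:
                    pc.fuse(world, room, nbr)
                    acted.add(room)
                    acted.add(nbr)
                    fused = True
                    break
        if fused:
            continue
        if world.u() < p.P_MC:
            if pc.move_protocell(world, r, c):
                acted.add(room)


def _phase_membranes(world: World) -> None:
    p = world.params
    rng = world.rng
    # membrane formation in eligible cell-free rooms
    eligible = np.argwhere(world.am >= p.L_AM)
    if eligible.size:
        order = rng.permutation(len(eligible))
        for i in order:
            r, c = int(eligible[i][0]), int(eligible[i][1])
            if (r, c) not in world.cells:
                pc.form_membrane(world, r, c)
    # exchange and permeation per cell
    rooms = list(world.cells)
    if len(rooms) > 1:
        rng.shuffle(rooms)
    for room in rooms:
        cell = world.cells.get(room)
        if cell is None:
            continue
        r, c = room
        i_ions = world.inner_ions(r, c)
        pc.exchange_amphiphiles(world, r, c, cell, i_ions)
        cell = world.cells.get(room)
        if cell is None:
            continue  # membrane collapsed during exchange
        pc.msp_membrane_exchange(world, r, c, cell)
        pc.permeate(world, r, c, cell, i_ions)


def _phase_polymers(world: World) -> None:
    rng = world.rng
    rooms = list(world.strands)
    if len(rooms) > 1:
        rng.shuffle(rooms)
    for r, c in rooms:
        rna.step_rna_room(world, r, c)
    rooms = list(world.strands)
    if len(rooms) > 1:
        rng.shuffle(rooms)
    for r, c in rooms:
        drt.step_drt_room(world, r, c)
    # free-peptide degradation wherever dipeptides exist
    pep_rooms = np.argwhere(world.pep.sum(axis=2) > 0)
    for r, c in pep_rooms:
        drt.degrade_peptides_room(world, int(r), int(c))
    # membrane MSP degradation
    for (r, c), cell in list(world.cells.items()):
        drt.degrade_membrane_msp(world, r, c, cell)


def _phase_chemistry(world: World) -> None:
    chemistry.step_monomer_chemistry(world)


# -- movement ---------------------------------------------------------------

def _diffuse_counts(world: World, arr: np.ndarray, prob: float,
                    blocked: np.ndarray) -> None:
    """Batched random-walk step for one count array.

    Each unit in an unblocked room attempts a move to a uniformly chosen
    4-neighbour with probability ``prob``; moves off-grid (reflecting
    boundary) or into a blocked room are cancelled.
    """
    rng = world.rng
    src = np.where(blocked, 0, arr)
    movers = np.zeros_like(src)
    mask = src > 0
    if not mask.any():
        return
    movers[mask] = rng.binomial(src[mask], prob)
    total = int(movers.sum())
    if total == 0:
        return
    dirs = rng.multinomial(movers[mask], np.full(4, 0.25))
    per_dir = np.zeros(movers.shape + (4,), dtype=np.int64)
    per_dir[mask] = dirs
    n = world.N
    for k, (dr, dc) in enumerate(((-1, 0), (1, 0), (0, -1), (0, 1))):
        mv = per_dir[..., k]
        if world.params.toroidal:
            dest_blocked = np.roll(np.roll(blocked, -dr, axis=0), -dc, axis=1)
            ok = np.where(dest_blocked, 0, mv)
            arr -= ok
            arr += np.roll(np.roll(ok, dr, axis=0), dc, axis=1)
            continue
        # reflecting boundary: build destination validity mask
        valid = np.ones((n, n), dtype=bool)
        if dr == -1:
            valid[0, :] = False
        elif dr == 1:
            valid[n - 1, :] = False
        if dc == -1:
            valid[:, 0] = False
        elif dc == 1:
            valid[:, n - 1] = False
        # destination blocked?
        dest_blocked = np.zeros((n, n), dtype=bool)
        if dr == -1:
            dest_blocked[1:, :] = blocked[:-1, :]
        elif dr == 1:
            dest_blocked[:-1, :] = blocked[1:, :]
        elif dc == -1:
            dest_blocked[:, 1:] = blocked[:, :-1]
        elif dc == 1:
            dest_blocked[:, :-1] = blocked[:, 1:]
        ok = np.where(valid & ~dest_blocked, mv, 0)
        arr -= ok
        if dr == -1:
            arr[:-1, :] += ok[1:, :]
        elif dr == 1:
            arr[1:, :] += ok[:-1, :]
        elif dc == -1:
            arr[:, :-1] += ok[:, 1:]
        elif dc == 1:
            arr[:, 1:] += ok[:, :-1]


def _diffuse_stack(world: World, stack: np.ndarray, prob: float,
                   blocked: np.ndarray) -> None:
    """``_diffuse_counts`` over a whole (S, N, N) species stack at once."""
    rng = world.rng
    src = np.where(blocked[None], 0, stack)
    mask = src > 0
    if not mask.any():
        return
    movers = np.zeros_like(src)
    movers[mask] = rng.binomial(src[mask], prob)
    if not movers.any():
        return
    dirs = rng.multinomial(movers[mask], np.full(4, 0.25))
    per_dir = np.zeros(movers.shape + (4,), dtype=np.int64)
    per_dir[mask] = dirs
    n = world.N
    for k, (dr, dc) in enumerate(((-1, 0), (1, 0), (0, -1), (0, 1))):
        mv = per_dir[..., k]
        if world.params.toroidal:
            dest_blocked = np.roll(np.roll(blocked, -dr, axis=0), -dc, axis=1)
            ok = np.where(dest_blocked[None], 0, mv)
            stack -= ok
            stack += np.roll(np.roll(ok, dr, axis=1), dc, axis=2)
            continue
        valid = np.ones((n, n), dtype=bool)
        if dr == -1:
            valid[0, :] = False
        elif dr == 1:
            valid[n - 1, :] = False
        if dc == -1:
            valid[:, 0] = False
        elif dc == 1:
            valid[:, n - 1] = False
        dest_blocked = np.zeros((n, n), dtype=bool)
        if dr == -1:
            dest_blocked[1:, :] = blocked[:-1, :]
        elif dr == 1:
            dest_blocked[:-1, :] = blocked[1:, :]
        elif dc == -1:
            dest_blocked[:, 1:] = blocked[:, :-1]
        elif dc == 1:
            dest_blocked[:, :-1] = blocked[:, 1:]
        ok = np.where((valid & ~dest_blocked)[None], mv, 0)
        stack -= ok
        if dr == -1:
            stack[:, :-1, :] += ok[:, 1:, :]
        elif dr == 1:
            stack[:, 1:, :] += ok[:, :-1, :]
        elif dc == -1:
            stack[:, :, :-1] += ok[:, :, 1:]
        elif dc == 1:
            stack[:, :, 1:] += ok[:, :, :-1]


def _phase_movement(world: World) -> None:
    p = world.params
    rng = world.rng
    blocked = np.zeros((world.N, world.N), dtype=bool)
    for (r, c) in world.cells:
        blocked[r, c] = True

    # monomers and precursors (mass 1), all species moved in one batch
    stack = np.concatenate([
        world.npre[None], world.apre[None], world.aapre[None],
        np.moveaxis(world.nt, 2, 0), np.moveaxis(world.aa, 2, 0),
    ])
    _diffuse_stack(world, stack, p.P_MV, blocked)
    world.npre[:, :] = stack[0]
    world.apre[:, :] = stack[1]
    world.aapre[:, :] = stack[2]
    world.nt[:, :, :] = np.moveaxis(stack[3:7], 0, 2)
    world.aa[:, :, :] = np.moveaxis(stack[7:13], 0, 2)

    # Free amphiphiles live outside every membrane (a protocell room's
    # exterior pool is am_out), so the combined ambient field diffuses
    # over all rooms with no membrane blocking; interior free amphiphiles
    # (world.am at protocell rooms) do not move between rooms.
    amb = np.where(blocked, world.am_out, world.am)
    if amb.any():
        none_blocked = np.zeros_like(blocked)
        _diffuse_counts(world, amb, p.P_MV, none_blocked)
        world.am_out = np.where(blocked, amb, 0)
        world.am = np.where(blocked, world.am, amb)

    # free dipeptides (mass 2)
    p_pep = polymer_move_probability(2, p)
    pep_any = world.pep.sum(axis=2)
    if pep_any.any():
        nz = np.nonzero(world.pep.sum(axis=(0, 1)))[0]
        for k in nz:
            _diffuse_counts(world, world.pep[:, :, k], p_pep, blocked)

    # RNA strands (per object)
    for room in list(world.strands):
        if blocked[room]:
            continue
        r, c = room
        lst = world.strands.get(room)
        if not lst:
            continue
        moved_any = False
        stay: List = []
        for s in lst:
            if world.u() < polymer_move_probability(s.mass, p):
                dr, dc = ((-1, 0), (1, 0), (0, -1), (0, 1))[int(world.u() * 4)]
                rr, cc = r + dr, c + dc
                if p.toroidal:
                    rr, cc = rr % world.N, cc % world.N
                if 0 <= rr < world.N and 0 <= cc < world.N \
                        and not blocked[rr, cc]:
                    world.strands.setdefault((rr, cc), []).append(s)
                    moved_any = True
                    continue
            stay.append(s)
        if moved_any:
            if stay:
                world.strands[room] = stay
            else:
                world.strands.pop(room, None)


_PHASES = (_phase_protocells, _phase_membranes, _phase_polymers,
           _phase_chemistry, _phase_movement)


def step(world: World) -> World:
    """Advance the world by one Monte Carlo step."""
    phases = list(_PHASES)
    if world.params.shuffle_phases:
        world.rng.shuffle(phases)
    for phase in phases:
        phase(world)
    world.step_count += 1
    return world


# --------------------------------------------------------------------------
# Run loop
# --------------------------------------------------------------------------

def run(world: World, scenario: Scenario, *, audit_every: int = 0,
        progress: bool = False) -> pd.DataFrame:
    """Execute a scenario: timed inoculations and parameter changes are
    applied before the phases of their exact step; a census row is emitted
    at step 0 and every ``report_every`` steps.

    ``audit_every`` > 0 additionally asserts exact material conservation at
    that cadence (used by the test suite).
    """
    from .observables import take_census
    from .scenarios import inoculate
    from .world import audit_conservation

    inocs = list(scenario.inoculations)
    sched = list(scenario.schedule)
    rows = [take_census(world)]
    iterator = range(world.step_count, scenario.total_steps)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator)
        except ImportError:
            pass
    for t in iterator:
        while inocs and inocs[0].step == t:
            inoculate(world, inocs.pop(0))
        while sched and sched[0][0] == t:
            _, name, value = sched.pop(0)
            world.params.set(name, value)
        rep = scenario.repeat
        if rep is not None and t >= rep.start \
                and (t - rep.start) % rep.interval == 0:
            used = set()
            for payload in rep.payloads:
                used |= inoculate(world, payload, exclude=used)
        step(world)
        if (t + 1) % scenario.report_every == 0:
            rows.append(take_census(world))
        if audit_every and (t + 1) % audit_every == 0:
            audit = audit_conservation(world)
            bad = {k: v for k, v in audit.items() if v[0] != v[1]}
            if bad:
                raise AssertionError(
                    f"conservation violated at step {world.step_count}: {bad}")
    return pd.DataFrame(rows)
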