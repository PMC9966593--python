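"""World state: the N x N room grid, polymers, protocells and the
conservation ledger.

Monomer-scale species are held in integer numpy arrays indexed by room so
the engine can batch i.i.d. Bernoulli events as binomial draws.  RNA
strands are Python objects (few hundred at the scales simulated); free
dipeptides are a per-room count array over the 36 ordered residue pairs.

A room occupied by a protocell stores the cell *interior* in the ordinary
room arrays; ambient (extra-cellular) amphiphiles sharing the room with a
membrane live in the separate ``am_out`` array, which is the pool the
membrane exchanges with and through which protocells compete for membrane
components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import (
    AA_INDEX, AA_TYPES, BASE_INDEX, BASES, Params, SequenceDefs, WC,
)

N_PAIRS = len(AA_TYPES) ** 2  # ordered dipeptide kinds


def pair_index(pair: str) -> int:
    return AA_INDEX[pair[0]] * len(AA_TYPES) + AA_INDEX[pair[1]]


def pair_from_index(idx: int) -> str:
    return AA_TYPES[idx // len(AA_TYPES)] + AA_TYPES[idx % len(AA_TYPES)]


class RNAStrand:
    """A single RNA molecule, possibly carrying a growing complement and
    bound amino acids / a bound dipeptide.

    ``seq`` is the template strand (its own 5'->3').  ``segs`` is a sorted
    list of ``[offset, pairing_string, pristine]``: ``pairing_string[k]``
    is the base paired to ``seq[offset + k]`` (stored in template
    coordinates; a released complement reads as the reverse of its pairing
    string); ``pristine`` is True while the segment is a single recruited
    substrate and False once template-directed ligation has fused it into
    a nascent chain (which can only leave as the full complement).
    ``bound`` maps a binding-site offset to a 1-letter amino acid or a
    2-letter dipeptide; a strand with anything bound is folded and exempt
    from attraction, degradation and random ligation.
    """

    __slots__ = ("seq", "segs", "bound", "_sites", "_labels")

    def __init__(self, seq: str, segs: Optional[List[list]] = None,
                 bound: Optional[Dict[int, str]] = None):
        if len(seq) < 2:
            raise ValueError("an RNA strand has at least 2 residues")
        self.seq = seq
        self.segs: List[list] = segs or []
        self.bound: Dict[int, str] = bound or {}
        self._sites = None   # cached binding sites (seq is immutable-ish)
        self._labels = None  # cached functional labels

    # -- derived ----------------------------------------------------------
    @property
    def folded(self) -> bool:
        return bool(self.bound)

    @property
    def paired_length(self) -> int:
        return sum(len(s[1]) for s in self.segs)

    @property
    def residues(self) -> int:
        """Nucleotide residues in the whole complex (template + complement)."""
        return len(self.seq) + self.paired_length

    @property
    def bound_residues(self) -> int:
        return sum(len(v) for v in self.bound.values())

    @property
    def mass(self) -> int:
        """Relative mass for movement: every nucleotide and amino-acid
        residue of the complex counts one unit."""
        return self.residues + self.bound_residues

    def paired_mask(self) -> np.ndarray:
        m = np.zeros(len(self.seq), dtype=bool)
        for seg in self.segs:
            m[seg[0]:seg[0] + len(seg[1])] = True
        return m

    def invalidate(self) -> None:
        self._sites = None
        self._labels = None

    def copy(self) -> "RNAStrand":
        return RNAStrand(self.seq, [list(s) for s in self.segs],
                         dict(self.bound))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"RNAStrand({self.seq!r}, segs={self.segs!r}, "
                f"bound={self.bound!r})")


@dataclass
class Protocell:
    """Membrane state of an occupied room: ``b`` amphiphiles (two layers,
    surface scale b/2) and ``p`` embedded membrane-stabilizing peptides."""

    b: int
    p: int = 0


@dataclass
class Ledger:
    """Expected material totals (initial + inoculated), in monomer
    equivalents, for the exact conservation audit."""

    nucleotide: int = 0
    amphiphile: int = 0
    amino_acid: int = 0
    inoculated_nucleotide: int = 0
    inoculated_amphiphile: int = 0
    inoculated_amino_acid: int = 0

    def add_inoculated(self, nucleotide=0, amphiphile=0, amino_acid=0) -> None:
        self.nucleotide += nucleotide
        self.amphiphile += amphiphile
        self.amino_acid += amino_acid
        self.inoculated_nucleotide += nucleotide
        self.inoculated_amphiphile += amphiphile
        self.inoculated_amino_acid += amino_acid


class World:
    """Complete mutable state of one simulation."""

    def __init__(self, params: Params, seq_defs: SequenceDefs,
                 rng: np.random.Generator):
        n = params.N
        self.params = params
        self.seq_defs = seq_defs
        self.rng = rng
        self.N = n
        self.step_count = 0
        # precursors
        self.npre = np.zeros((n, n), dtype=np.int64)
        self.apre = np.zeros((n, n), dtype=np.int64)
        self.aapre = np.zeros((n, n), dtype=np.int64)
        # monomers
        self.nt = np.zeros((n, n, 4), dtype=np.int64)    # free nucleotides
        self.am = np.zeros((n, n), dtype=np.int64)       # free amphiphiles
        self.am_out = np.zeros((n, n), dtype=np.int64)   # ambient, cell rooms
        self.aa = np.zeros((n, n, 6), dtype=np.int64)    # free amino acids
        # free dipeptides by ordered pair
        self.pep = np.zeros((n, n, N_PAIRS), dtype=np.int64)
        # polymers and cells
        self.strands: Dict[Tuple[int, int], List[RNAStrand]] = {}
        self.cells: Dict[Tuple[int, int], Protocell] = {}
        self.ledger = Ledger()
        self.event_log: List[dict] = []
        # buffered uniform stream (single RNG, drawn in blocks for speed)
        self._ubuf: list = []
        self._ui = 0

    def u(self) -> float:
        """Next uniform variate from the world's single RNG stream."""
        i = self._ui
        if i >= len(self._ubuf):
            self._ubuf = self.rng.random(16384).tolist()
            i = 0
        self._ui = i + 1
        return self._ubuf[i]

    def binom(self, n: int, p: float) -> int:
        """Binomial(n, p) from the buffered uniform stream (exact CDF
        inversion) when the expected count is small, else the generator's
        own sampler."""
        if n <= 0 or p <= 0.0:
            return 0
        if p >= 1.0:
            return n
        if n * p <= 10.0:
            u = self.u()
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
        return int(self.rng.binomial(n, p))

    def split4(self, n: int):
        """Multinomial(n; 1/4,1/4,1/4,1/4) via conditional binomials."""
        a = self.binom(n, 0.25)
        b = self.binom(n - a, 1.0 / 3.0)
        c = self.binom(n - a - b, 0.5)
        return a, b, c, n - a - b - c

    # -- room helpers ------------------------------------------------------
    def room_strands(self, r: int, c: int) -> List[RNAStrand]:
        return self.strands.get((r, c), [])

    def add_strand(self, r: int, c: int, strand: RNAStrand) -> None:
        self.strands.setdefault((r, c), []).append(strand)

    def remove_strand(self, r: int, c: int, strand: RNAStrand) -> None:
        lst = self.strands[(r, c)]
        lst.remove(strand)
        if not lst:
            del self.strands[(r, c)]

    def neighbors(self, r: int, c: int):
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if self.params.toroidal:
                yield rr % self.N, cc % self.N
            elif 0 <= rr < self.N and 0 <= cc < self.N:
                yield rr, cc

    def inner_ions(self, r: int, c: int) -> int:
        """i: impermeable-ion quantity of a room = free nucleotides plus all
        nucleotide residues of RNA complexes (template and complement)."""
        nt = self.nt[r, c]
        i = int(nt[0] + nt[1] + nt[2] + nt[3])
        for s in self.strands.get((r, c), ()):
            i += len(s.seq)
            for seg in s.segs:
                i += len(seg[1])
        return i

    # -- conservation ------------------------------------------------------
    def observed_totals(self) -> dict:
        nt_total = int(self.npre.sum() + self.nt.sum())
        aa_total = int(self.aapre.sum() + self.aa.sum() + 2 * self.pep.sum())
        am_total = int(self.apre.sum() + self.am.sum() + self.am_out.sum())
        for lst in self.strands.values():
            for s in lst:
                nt_total += s.residues
                aa_total += s.bound_residues
        for cell in self.cells.values():
            am_total += cell.b
            aa_total += 2 * cell.p
        return {
            "nucleotide": nt_total,
            "amphiphile": am_total,
            "amino_acid": aa_total,
        }

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "step_count": self.step_count,
            "params": self.params.to_dict(),
            "seq_defs": self.seq_defs.to_dict(),
            "rng_state": self.rng.bit_generator.state,
            "npre": self.npre.tolist(),
            "apre": self.apre.tolist(),
            "aapre": self.aapre.tolist(),
            "nt": self.nt.tolist(),
            "am": self.am.tolist(),
            "am_out": self.am_out.tolist(),
            "aa": self.aa.tolist(),
            "pep": self.pep.tolist(),
            "strands": {
                f"{r},{c}": [
                    {"seq": s.seq, "segs": [list(seg) for seg in s.segs],
                     "bound": {str(k): v for k, v in s.bound.items()}}
                    for s in lst
                ]
                for (r, c), lst in self.strands.items()
            },
            "cells": {f"{r},{c}": {"b": cell.b, "p": cell.p}
                      for (r, c), cell in self.cells.items()},
            "ledger": {
                "nucleotide": self.ledger.nucleotide,
                "amphiphile": self.ledger.amphiphile,
                "amino_acid": self.ledger.amino_acid,
                "inoculated_nucleotide": self.ledger.inoculated_nucleotide,
                "inoculated_amphiphile": self.ledger.inoculated_amphiphile,
                "inoculated_amino_acid": self.ledger.inoculated_amino_acid,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "World":
        params = Params(**d["params"])
        seq_defs = SequenceDefs.from_dict(d["seq_defs"])
        rng = np.random.default_rng()
        rng.bit_generator.state = d["rng_state"]
        w = cls(params, seq_defs, rng)
        w.step_count = d["step_count"]
        for name in ("npre", "apre", "aapre", "nt", "am", "am_out", "aa",
                     "pep"):
            setattr(w, name, np.asarray(d[name], dtype=np.int64))
        for key, lst in d["strands"].items():
            r, c = map(int, key.split(","))
            w.strands[(r, c)] = [
                RNAStrand(s["seq"], [list(seg) for seg in s["segs"]],
                          {int(k): v for k, v in s["bound"].items()})
                for s in lst
            ]
        for key, cell in d["cells"].items():
            r, c = map(int, key.split(","))
            w.cells[(r, c)] = Protocell(b=cell["b"], p=cell["p"])
        w.ledger = Ledger(**d["ledger"])
        return w

    def save_checkpoint(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load_checkpoint(cls, path) -> "World":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def init_world(params: Params, seq_defs: Optional[SequenceDefs] = None,
               seed=0) -> World:
    """Fresh world: the three precursor stocks scattered uniformly at
    random over the rooms; no polymers, no protocells."""
    from .config import default_sequence_defs

    if seq_defs is None:
        seq_defs = default_sequence_defs(0)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    w = World(params, seq_defs, rng)
    n2 = params.N * params.N
    for arr, total in ((w.npre, params.T_NPB), (w.apre, params.T_APB),
                       (w.aapre, params.T_AAPB)):
        counts = rng.multinomial(total, np.full(n2, 1.0 / n2))
        arr += counts.reshape(params.N, params.N)
    w.ledger.nucleotide = params.T_NPB
    w.ledger.amphiphile = params.T_APB
    w.ledger.amino_acid = params.T_AAPB
    return w


def audit_conservation(world: World) -> dict:
    """Per material class: (expected, observed) monomer-equivalent totals.

    Expected = initial stock + everything added by inoculation.  The
    identity is exact (integers); any discrepancy indicates an accounting
    bug in an event implementation.
    """
    observed = world.observed_totals()
    expected = {
        "nucleotide": world.ledger.nucleotide,
        "amphiphile": world.ledger.amphiphile,
        "amino_acid": world.ledger.amino_acid,
    }
    return {k: (expected[k], observed[k]) for k in expected}
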