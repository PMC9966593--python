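"""Parameter set, sequence definitions and scenario descriptions.

``Params`` carries every event probability and system constant with the
published default values.  ``SequenceDefs`` fixes the actual nucleotide
sequences of the amino-acid binding sites (the "codebook"), the dipeptide
gene motifs derived from them, and the ribozyme/control motifs.  The model
only prescribes the *lengths* of these sequences, so concrete sequences are
configuration with a deterministic shipped default.  ``Scenario`` describes
a runnable experiment: initial materials, timed inoculations, timed
parameter changes, and output cadence.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

#: RNA alphabet, index order used throughout the package.
BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Watson-Crick partner of each base.
WC = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: The six prebiotic amino-acid types of the model.
AA_TYPES = "PQRSTL"
AA_INDEX = {a: i for i, a in enumerate(AA_TYPES)}


def reverse_complement(seq: str) -> str:
    return "".join(WC[b] for b in reversed(seq))


# --------------------------------------------------------------------------
# Params
# --------------------------------------------------------------------------

_PROBABILITY_FIELDS = (
    "P_AD", "P_AF", "P_AJM", "P_ALM", "P_APP", "P_AT", "P_BB", "P_CB",
    "P_CD", "P_CF", "P_FP", "P_MC", "P_MF", "P_MV", "P_ND", "P_NDE",
    "P_NF", "P_NFR", "P_NPP", "P_RL", "P_SP", "P_TL",
    "P_AABR", "P_AAD", "P_AADE", "P_AAF", "P_AAPP", "P_AATL", "P_NFP",
    "P_PBB", "P_PJM", "P_PLM", "P_PLR",
)

_COUNT_FIELDS = ("N", "T_NPB", "T_APB", "T_AAPB", "L_AM", "L_NSR", "L_AABS", "L_TMPL")


@dataclass
class Params:
    """All event probabilities and system constants of the model,
    with the published values as defaults.

    Probabilities are per entity per Monte Carlo step.  ``F_DO`` scales
    nucleotide/RNA degradation outside protocells, ``F_DW`` scales
    amphiphile/membrane-peptide degradation inside the membrane, ``F_MSP``
    sets the strength of the membrane-stabilizing-peptide effect.
    """

    # -- protocell / RNA world probabilities -------------------------------
    P_AD: float = 0.01      # amphiphile decays to precursor
    P_AF: float = 0.02      # amphiphile forms from precursor
    P_AJM: float = 0.2      # amphiphile joins membrane
    P_ALM: float = 0.001    # amphiphile leaves membrane (base rate)
    P_APP: float = 0.9      # amphiphile precursor permeation
    P_AT: float = 0.9       # template attracts a substrate
    P_BB: float = 1e-5      # phosphodiester bond break
    P_CB: float = 2e-4      # protocell breaks
    P_CD: float = 0.05      # protocell divides (base rate)
    P_CF: float = 0.001     # adjacent protocells fuse
    P_FP: float = 1e-4      # false base-pairing during attraction
    P_MC: float = 0.1       # protocell moves
    P_MF: float = 0.1       # membrane forms (base rate)
    P_MV: float = 0.9       # monomer/precursor moves
    P_ND: float = 0.05      # nucleotide decays
    P_NDE: float = 0.001    # chain-end nucleotide residue decays
    P_NF: float = 0.02      # nucleotide forms (non-enzymatic)
    P_NFR: float = 0.5      # nucleotide forms, NSR-catalyzed
    P_NPP: float = 0.5      # nucleotide precursor permeation (base rate)
    P_RL: float = 1e-6      # random ligation per candidate end pair
    P_SP: float = 0.5       # separation of a single base pair
    P_TL: float = 0.5       # template-directed ligation per junction
    # -- amino acid / peptide / DRT probabilities --------------------------
    P_AABR: float = 0.9     # amino acid binds its RNA site
    P_AAD: float = 0.2      # amino acid decays
    P_AADE: float = 0.1     # peptide chain-end residue decays
    P_AAF: float = 0.1      # amino acid forms from precursor
    P_AAPP: float = 0.9     # amino acid precursor permeation
    P_AATL: float = 0.5     # on-template amino-acid ligation (DRT)
    P_NFP: float = 0.5      # nucleotide forms, NSP-catalyzed
    P_PBB: float = 0.01     # peptide bond breaks
    P_PJM: float = 0.9      # MSP joins membrane
    P_PLM: float = 0.1      # MSP leaves membrane
    P_PLR: float = 0.2      # amino acid/peptide leaves the RNA template
    # -- constants ---------------------------------------------------------
    N: int = 30             # grid side length
    T_NPB: int = 50_000     # initial nucleotide precursors
    T_APB: int = 50_000     # initial amphiphile precursors
    T_AAPB: int = 50_000    # initial amino-acid precursors
    F_DO: float = 20.0      # degradation factor outside protocells (>= 1)
    F_DW: float = 0.1       # degradation factor within membrane (0 < . <= 1)
    F_MSP: float = 1.0      # MSP-effect factor (>= 0)
    L_AM: int = 200         # membrane-formation amphiphile threshold
    L_NSR: int = 10         # NSR characteristic-domain length (nt)
    L_AABS: int = 5         # amino-acid-binding-site length (nt)
    L_TMPL: int = 10        # min template length to nucleate a complement
    # -- implementation switches (documented, not part of the published set)
    toroidal: bool = False        # grid wrap-around (default: reflecting)
    shuffle_phases: bool = False  # randomize phase order (robustness runs)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v!r}")
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.F_DO < 1.0:
            raise ValueError(f"F_DO must be >= 1, got {self.F_DO!r}")
        if not (0.0 < self.F_DW <= 1.0):
            raise ValueError(f"F_DW must be in (0, 1], got {self.F_DW!r}")
        if self.F_MSP < 0.0:
            raise ValueError(f"F_MSP must be >= 0, got {self.F_MSP!r}")

    def replace(self, **overrides) -> "Params":
        """Return a copy with the given fields replaced (re-validated)."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def set(self, name: str, value) -> None:
        """In-place override used by parameter schedules."""
        if name not in {f.name for f in dataclasses.fields(self)}:
            raise ValueError(f"unknown parameter: {name}")
        setattr(self, name, _coerce_field(self, name, value))
        self.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in dataclasses.fields(cls))


def _coerce_field(params: Params, name: str, value):
    current = getattr(params, name)
    if isinstance(current, bool):
        if isinstance(value, str):
            return value.strip().lower() in ("1", "true", "yes", "on")
        return bool(value)
    if isinstance(current, (int, np.integer)):
        return int(value)
    return float(value)


def load_params(source=None, overrides: Optional[Mapping[str, object]] = None) -> Params:
    """Build a validated ``Params`` from YAML text/stream/dict plus overrides.

    Unspecified fields take the published defaults; overrides win over the
    source.  Unknown names or out-of-range values raise ``ValueError``
    naming the offending field.
    """
    data: dict = {}
    if source is not None:
        if isinstance(source, Mapping):
            data = dict(source)
        else:
            text = source.read() if hasattr(source, "read") else str(source)
            loaded = yaml.safe_load(text) if text.strip() else None
            if loaded is None:
                data = {}
            elif isinstance(loaded, Mapping):
                data = dict(loaded)
            else:
                raise ValueError("params source must parse to a mapping")
    if overrides:
        data.update(overrides)
    known = set(Params.field_names())
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
    base = Params()
    coerced = {k: _coerce_field(base, k, v) for k, v in data.items()}
    return Params(**coerced)


def save_params(params: Params) -> str:
    """Serialize to YAML; ``load_params(save_params(p)) == p``."""
    return yaml.safe_dump(params.to_dict(), sort_keys=True)


# --------------------------------------------------------------------------
# SequenceDefs
# --------------------------------------------------------------------------

#: Gene/RNA labels used throughout: membrane-stabilizing peptide gene,
#: nucleotide synthetase peptide gene, control peptide gene, nucleotide
#: synthetase ribozyme, control (non-coding) RNA.
GENE_LABELS = ("MSPG", "NSPG", "CTPG", "NSR", "CTR")


@dataclass(frozen=True)
class SequenceDefs:
    """Concrete sequences behind the model's abstract motifs.

    ``codebook`` maps one binding-site 5-mer to each of the six amino-acid
    types.  A dipeptide gene is the exact concatenation of the two sites of
    its ordered amino-acid pair.  ``nsr_motif`` is the ribozyme's
    characteristic domain; ``control_rna_motif`` encodes nothing.
    """

    codebook: dict            # 5-mer -> amino-acid letter (6 entries)
    msp_pair: str             # e.g. "PQ": ordered residues of the MSP
    nsp_pair: str
    control_pair: str
    nsr_motif: str            # 10-mer
    control_rna_motif: str    # 10-mer

    def site(self, aa: str) -> str:
        """Binding-site 5-mer of an amino-acid type."""
        for k, v in self.codebook.items():
            if v == aa:
                return k
        raise KeyError(aa)

    def gene_motif(self, pair: str) -> str:
        return self.site(pair[0]) + self.site(pair[1])

    @property
    def mspg_motif(self) -> str:
        return self.gene_motif(self.msp_pair)

    @property
    def nspg_motif(self) -> str:
        return self.gene_motif(self.nsp_pair)

    @property
    def ctpg_motif(self) -> str:
        return self.gene_motif(self.control_pair)

    def motif_for(self, label: str) -> str:
        return self.all_motifs()[label]

    def all_motifs(self) -> dict:
        cached = getattr(self, "_motif_cache", None)
        if cached is None:
            cached = {
                "MSPG": self.mspg_motif,
                "NSPG": self.nspg_motif,
                "CTPG": self.ctpg_motif,
                "NSR": self.nsr_motif,
                "CTR": self.control_rna_motif,
            }
            object.__setattr__(self, "_motif_cache", cached)
        return cached

    def validate(self, l_aabs: int = 5, l_nsr: int = 10) -> None:
        if len(self.codebook) != len(AA_TYPES):
            raise ValueError("codebook must have one site per amino-acid type")
        if sorted(self.codebook.values()) != sorted(AA_TYPES):
            raise ValueError("codebook values must be the six amino-acid types")
        sites = list(self.codebook)
        if any(len(s) != l_aabs for s in sites):
            raise ValueError(f"all binding sites must have length {l_aabs}")
        if len(set(sites)) != len(sites):
            raise ValueError("binding sites must be pairwise distinct")
        motifs = self.all_motifs()
        if len(set(motifs.values())) != len(motifs):
            raise ValueError("gene/RNA motifs must be pairwise distinct")
        for name, m in motifs.items():
            if len(m) != l_nsr:
                raise ValueError(f"{name} motif must have length {l_nsr}")
            if m == reverse_complement(m):
                raise ValueError(f"{name} motif is its own reverse complement")
        # non-coding motifs must not accidentally carry a binding site, and
        # no motif's reverse complement may carry one (otherwise that
        # motif's replication intermediate would bind amino acids, fold,
        # and break the copy-back loop)
        for name in ("NSR", "CTR"):
            m = motifs[name]
            for i in range(len(m) - l_aabs + 1):
                if m[i:i + l_aabs] in self.codebook:
                    raise ValueError(f"{name} motif contains a binding site")
        for name, m in motifs.items():
            rc = reverse_complement(m)
            for i in range(len(rc) - l_aabs + 1):
                if rc[i:i + l_aabs] in self.codebook:
                    raise ValueError(
                        f"{name} motif's reverse complement contains a "
                        f"binding site")
        # balanced base composition: genes must not occupy private
        # nucleotide niches, or concrete sequence choices would bias the
        # competition experiments the motifs exist for
        lo = l_nsr // 4 - 1
        hi = -(-l_nsr // 4) + 1
        for name, m in motifs.items():
            counts = [m.count(b) for b in BASES]
            if min(counts) < lo or max(counts) > hi:
                raise ValueError(
                    f"{name} motif base composition {counts} is unbalanced")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SequenceDefs":
        defs = cls(
            codebook=dict(d["codebook"]),
            msp_pair=d["msp_pair"],
            nsp_pair=d["nsp_pair"],
            control_pair=d["control_pair"],
            nsr_motif=d["nsr_motif"],
            control_rna_motif=d["control_rna_motif"],
        )
        defs.validate()
        return defs


def default_sequence_defs(rng_seed: int = 0, l_aabs: int = 5,
                          l_nsr: int = 10) -> SequenceDefs:
    """Deterministically generate a valid ``SequenceDefs`` from a seed.

    Sites and motifs are drawn uniformly and redrawn until every invariant
    holds (distinctness, no self-reverse-complement, no binding site inside
    the non-coding motifs).  Seed 0 is the shipped package default.
    """
    rng = np.random.default_rng(rng_seed)

    def rand_seq(k: int) -> str:
        return "".join(BASES[i] for i in rng.integers(0, 4, size=k))

    for _ in range(10_000):
        sites = []
        while len(sites) < len(AA_TYPES):
            s = rand_seq(l_aabs)
            if s not in sites:
                sites.append(s)
        codebook = {s: a for s, a in zip(sites, AA_TYPES)}
        extras = []
        while len(extras) < 2:
            m = rand_seq(l_nsr)
            if any(m[i:i + l_aabs] in codebook
                   for i in range(l_nsr - l_aabs + 1)):
                continue
            extras.append(m)
        defs = SequenceDefs(
            codebook=codebook,
            msp_pair="PQ",
            nsp_pair="RS",
            control_pair="TL",
            nsr_motif=extras[0],
            control_rna_motif=extras[1],
        )
        try:
            defs.validate(l_aabs=l_aabs, l_nsr=l_nsr)
        except ValueError:
            continue
        return defs
    raise RuntimeError("could not generate valid sequence definitions")


# --------------------------------------------------------------------------
# Scenario
# --------------------------------------------------------------------------

@dataclass
class Inoculation:
    """A timed addition of material to the world.

    kind "protocells": ``count`` vesicles of membrane size 2*L_AM in random
    protocell-free rooms, each loaded with ``genes`` (label -> copies).
    kind "vesicle": shorthand for empty protocells (no genes).
    kind "gene": one RNA copy of ``gene`` into a random protocell whose
    gene-content signature contains ``target`` (a set of labels; empty set
    targets protocells carrying no labelled gene).
    """

    step: int
    kind: str = "protocells"
    count: int = 1
    genes: dict = field(default_factory=dict)
    gene: Optional[str] = None
    target: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.kind not in ("protocells", "vesicle", "gene"):
            raise ValueError(f"unknown inoculation kind {self.kind!r}")
        if self.kind == "gene" and not self.gene:
            raise ValueError("gene inoculation needs a gene label")
        for g in list(self.genes) + ([self.gene] if self.gene else []):
            if g not in GENE_LABELS:
                raise ValueError(f"unknown gene label {g!r}")
        if self.target is not None:
            self.target = frozenset(self.target)
            unknown = self.target - set(GENE_LABELS)
            if unknown:
                raise ValueError(f"unknown target labels {sorted(unknown)}")


@dataclass
class RepeatRule:
    """Repeating gene inoculations: from ``start`` every ``interval`` steps,
    apply each payload (kind 'gene') to a distinct eligible protocell."""

    start: int
    interval: int
    payloads: list = field(default_factory=list)


@dataclass
class Scenario:
    name: str = "custom"
    total_steps: int = 10_000
    report_every: int = 100
    inoculations: list = field(default_factory=list)
    schedule: list = field(default_factory=list)   # (step, param name, value)
    repeat: Optional[RepeatRule] = None

    def __post_init__(self) -> None:
        steps = [i.step for i in self.inoculations]
        if steps != sorted(steps):
            raise ValueError("inoculation steps must be non-decreasing")
        sched_steps = [s for s, _, _ in self.schedule]
        if sched_steps != sorted(sched_steps):
            raise ValueError("schedule steps must be non-decreasing")
        known = set(Params.field_names())
        for _, name, _ in self.schedule:
            if name not in known:
                raise ValueError(f"schedule names unknown parameter {name!r}")

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "total_steps": int(self.total_steps),
            "report_every": int(self.report_every),
            "inoculations": [
                {
                    "step": int(i.step),
                    "kind": i.kind,
                    "count": int(i.count),
                    "genes": {k: int(v) for k, v in i.genes.items()},
                    "gene": i.gene,
                    "target": sorted(i.target) if i.target is not None else None,
                }
                for i in self.inoculations
            ],
            "schedule": [[int(s), n, v] for s, n, v in self.schedule],
        }
        if self.repeat is not None:
            d["repeat"] = {
                "start": int(self.repeat.start),
                "interval": int(self.repeat.interval),
                "payloads": [
                    {"gene": p.gene,
                     "target": sorted(p.target) if p.target is not None else None}
                    for p in self.repeat.payloads
                ],
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        inocs = [
            Inoculation(
                step=i["step"],
                kind=i.get("kind", "protocells"),
                count=i.get("count", 1),
                genes=dict(i.get("genes") or {}),
                gene=i.get("gene"),
                target=(frozenset(i["target"]) if i.get("target") is not None
                        else None),
            )
            for i in d.get("inoculations", [])
        ]
        repeat = None
        if d.get("repeat"):
            r = d["repeat"]
            repeat = RepeatRule(
                start=r["start"],
                interval=r["interval"],
                payloads=[
                    Inoculation(
                        step=r["start"], kind="gene", gene=p["gene"],
                        target=(frozenset(p["target"])
                                if p.get("target") is not None else None),
                    )
                    for p in r.get("payloads", [])
                ],
            )
        return cls(
            name=d.get("name", "custom"),
            total_steps=d.get("total_steps", 10_000),
            report_every=d.get("report_every", 100),
            inoculations=inocs,
            schedule=[tuple(s) for s in d.get("schedule", [])],
            repeat=repeat,
        )


def load_scenario(source) -> Scenario:
    """Load a scenario from YAML text/stream/dict, or by preset name."""
    if isinstance(source, Mapping):
        return Scenario.from_dict(source)
    text = source.read() if hasattr(source, "read") else str(source)
    stripped = text.strip()
    if "\n" not in stripped and ":" not in stripped:
        from . import scenarios  # late import to avoid a cycle
        if stripped in scenarios.PRESET_NAMES:
            return scenarios.preset(stripped)[1]
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, Mapping):
        raise ValueError("scenario source must parse to a mapping")
    return Scenario.from_dict(loaded)


def save_scenario(scenario: Scenario) -> str:
    return yaml.safe_dump(scenario.to_dict(), sort_keys=True)
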