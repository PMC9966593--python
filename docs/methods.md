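# Methods

## Model

`drtworld` simulates an RNA/peptides-world scenario: protocells on an
`N x N` lattice whose RNA genes encode functional dipeptides through the
direct RNA template (DRT) mechanism. One Monte Carlo step applies five
phases in a fixed order — (1) protocell events (break, divide, fuse,
move), (2) membrane assembly/exchange and precursor permeation, (3)
polymer events (RNA degradation, random ligation, template-directed
synthesis, DRT peptide synthesis, peptide degradation), (4) monomer
chemistry, (5) movement of free entities. Within a phase entities are
visited in randomized order; every event is an independent Bernoulli trial
per entity per step. Identical i.i.d. monomer events are batched as
binomial draws per room, and scalar event decisions draw from one buffered
uniform stream; both are statistically identical to per-molecule coin
flips (the binomial batching is asserted by test) and all randomness flows
from a single seeded generator, so runs are bit-reproducible.

Three standing simplifications, inherited from the modelled system:
peptides never exceed two residues; amino acids never ligate off-template;
an RNA holding bound amino acids or a peptide is "folded" — it cannot
attract substrates, degrade, or randomly ligate, and its cargo is
protected too.

Energy is implicit (monomers are always activated); the only scarcity is
material, enforced by an exact integer conservation ledger per class
(nucleotide, amphiphile, amino-acid equivalents). Every event
implementation preserves the ledger identity exactly; the engine can
re-audit after every phase.

## Parameters

All event probabilities and size constants live in `Params`, with the
published defaults (e.g. `P_AT = 0.9` substrate attraction, `P_SP = 0.5`
separation of one base pair, `P_ALM = 0.001` amphiphile desorption,
`L_AM = 200` membrane threshold, 50,000 of each precursor on a 30 x 30
grid). Derived room factors are recomputed on demand and never cached
across events: inner impermeable ions `i` (free nucleotides + all RNA
residues), `x = a - L_AM + 1`, `y = 1 + i/(b/2)^(3/2)`,
`z = 1 + F_MSP*p`, `r = n^(1/2)`.

Two implementation constants extend the published set:

- `L_TMPL` (default 10 nt): the minimum template length able to nucleate a
  new complement. Shorter chains still serve as substrates, pair onto
  growing complements and degrade, but cannot found their own replication
  complex. Without a nucleation floor, the 2-9-mer fragments produced by
  chain-end erosion replicate as efficiently as genes, soak up the entire
  nucleotide flux and drive every functional sequence extinct; a stem of
  roughly the characteristic-domain length is also what stable duplex
  nucleation plausibly requires.
- `toroidal` (default off): grid boundary topology. The default reflecting
  boundary cancels off-grid moves.

## Sequences

The model prescribes lengths, not sequences, so concrete sequences are
configuration (`SequenceDefs`) with a deterministic shipped default
(seed 0). Invariants enforced at validation: six distinct binding-site
5-mers, one per amino-acid type; gene motifs are exact concatenations of
their two sites; all five motifs distinct, none self-reverse-complement;
the non-coding motifs (NSR, control RNA) contain no binding site; **no
motif's reverse complement contains a binding site** (otherwise that
gene's replication intermediate binds amino acids, folds, and cannot be
copied back — the shipped default would otherwise silently cripple one
gene); and every motif has an approximately balanced base composition
(each base 1-4 of 10), so no gene occupies a private nucleotide niche that
would bias the competition experiments.

## Replication kinetics

Attraction is base-pairing driven. Template side: each growth position of
the complement (one uniformly chosen nucleation position on a bare
template) recruits with `P_AT` the Watson-Crick-matching free nucleotide;
with `P_FP` a mismatching base is accepted instead (mutation). When no
fitting monomer is free, a fully pairing free oligomer from the room is
recruited into the nascent chain (fragment recycling; mismatching
oligomers are not pursued, their joint acceptance `P_FP**k` being
negligible against the monomer channel). Separation follows the model's
wording strictly: an *unligated* substrate leaves with `P_SP**sqrt(n)`,
and a ligated stretch only once it spans the full template (the complete
complementary chain). Segments therefore carry a provenance flag; ligation
clears it. A released complement reads as the reverse of its pairing
string, so function (sense-strand only) returns only after a second
copying round.

Two earlier designs were rejected on behaviour: a single count-weighted
substrate pick per template per step (junk oligomers dominate the pick,
starve monomer recruitment, and replication never outpaces degradation),
and free bidirectional oligomer hybridization (a futile anneal/separate
cycle plus chimeric ligation products). Chain-end decay (`P_NDE`) is one
trial per chain per step on a random unprotected end; the per-end reading
doubles erosion and pushes the replication/degradation balance below
break-even everywhere.

DRT synthesis runs bind -> ligate -> release in sequence within the
polymer phase (the phase already applies several distinct operations to a
strand); sites covered by the growing complement are double-stranded and
cannot bind amino acids.

## Protocells

A membrane separates its room's interior from the rest of the world. Free
amphiphiles are ambient — they diffuse across all rooms, including the
exterior pool of membrane-occupied rooms, which is the pool membranes
exchange with (`P_AJM` in, `P_ALM/(y*z)` out); this is the channel through
which protocells compete for membrane components. All other species
respect the membrane: movement never crosses it; precursors permeate
to/from the four neighbouring rooms with the permeation kernels (the same
expression in both directions); nucleotides, RNA, amino acids and peptides
never cross. Division sends a binomially assorted daughter into an
adjacent protocell-free room (displaced free molecules are pushed to a
neighbouring free room, or engulfed if none exists); a membrane whose last
amphiphile is lost dissolves in place.

## What the reduced-scale experiments show

The full-scale experiments run on a 30 x 30 grid for 10^5-10^6 steps
(hours of compute). The test suite instead runs the spread/ablation
experiments on an 8 x 8 grid with 5,000 nucleotide and amino-acid
precursors, 8,000 amphiphile precursors (so membranes at the published
`L_AM = 200` threshold keep growing and dividing), three inoculated
protocells and 8 x 10^3 steps — the longest horizon the suite can afford.
These conditions were chosen once for expressiveness, not fitted to
outcomes.

Reduced scale keeps: exact conservation, the full event set, the
replication/degradation balance, gene spread through protocell growth and
division. It does not keep the slow selection phenomena. The selection
clock is set by `P_ALM = 0.001`: a protocell without the
membrane-stabilizing peptide sheds its membrane over ~10^3 steps only once
ambient amphiphiles are exhausted, and purging a co-inoculated parasite
gene (or driving an ablated gene to absolute extinction) takes many such
generations — of order 5 x 10^4 to 10^5 steps in this implementation,
beyond the affordable horizon. The corresponding end-state assertions in
the acceptance tests are therefore expected to fail at this scale: what
the affordable runs do show reliably is the spread itself (three
inoculated protocells grow to ~20+ MSPG-carrying protocells), exact
conservation throughout, and the kernel-level MSP advantage (strictly
higher expected net amphiphile gain, asserted in closed form). The
full-scale presets remain available for overnight runs. Also exercised
only as presets plus a truncated smoke run: the ribozyme-takeover
experiments (gene inoculations start at step 2 x 10^5).

## Numerical choices

- Small-count binomials are sampled by exact CDF inversion of one buffered
  uniform; large counts use the generator's sampler. Conditional
  distributions (e.g. degradation given at least one event) are sampled by
  exact conditional inversion, never by rejection.
- Probability caps at 1 are explicit (permeation, F_DO-scaled rates).
- A membrane with `b < 2` uses `b = 2` in the desorption kernel (the pure
  kernel raises on `b < 2`); `b = 0` dissolves the protocell.
- Division clamps each daughter to at least one membrane amphiphile.
- Ties and orders: entities shuffle within phases; the phase order itself
  is fixed (protocells -> membranes -> polymers -> chemistry -> movement)
  so transport kernels see start-of-step membrane state; a config flag
  (`shuffle_phases`) randomizes it for robustness experiments.

## Known limitations

- No secondary structure: folding is the boolean proxy the model defines.
- Motif function is all-or-nothing (exact substring); no partial activity.
- Concrete sequence choice still influences kinetics weakly (composition
  balance bounds but does not eliminate it).
- The permeation direction convention (identical kernel inward and
  outward, neighbouring rooms as "outside") is one of several defensible
  discretizations; it conserves exactly and is symmetric in expectation.
- Checkpoint resume restarts the uniform buffer, so a resumed run is a
  valid but different sample path from the uninterrupted one.
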