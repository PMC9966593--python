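# drtworld

A Monte Carlo simulator of RNA-based protocells in which RNA genes encode
functional dipeptides through the **direct RNA template (DRT)** mechanism —
the hypothesis that an RNA with characteristic subsequences can bind
specific amino acids and promote their ligation into a peptide, moving
hereditary information from RNA into peptides without any translation
apparatus.

The package is for researchers in prebiotic evolution / artificial life who
want to re-run, extend or probe protocell-level selection experiments of
this kind: the spread of protocells carrying a membrane-stabilizing-peptide
gene (MSPG), its cooperation with a nucleotide synthetase ribozyme (NSR),
and the functional takeover of the ribozyme by a peptide gene (NSPG).

## The model

The world is an `N x N` lattice of rooms holding precursors and molecules
of three material classes — nucleotides, amphiphiles, amino acids — each
conserved exactly (integer ledger). Per Monte Carlo step, every entity
undergoes Bernoulli events with the model's probabilities (Table of
defaults in `drtworld.config.Params`):

- **Chemistry** — precursors form monomers (`P_NF`, `P_AF`, `P_AAF`),
  monomers decay back (`P_ND`, `P_AD`, `P_AAD`); an NSR ribozyme or NSP
  peptide in the room raises nucleotide formation to `P_NFR` / `P_NFP`.
- **RNA replication** — a template attracts substrates by base-pairing
  (`P_AT`) with mutation rate `P_FP` per base; aligned substrates ligate
  (`P_TL`); a substrate or the full complementary chain separates with
  `P_SP**sqrt(n)`. Phosphodiester bonds break with `P_BB` (squared in
  duplex regions), chain ends erode with `P_NDE`; outside protocells
  nucleotide/RNA degradation scales by `F_DO`.
- **DRT peptide synthesis** — amino acids bind characteristic 5-nt sites
  (`P_AABR`), adjacent residues ligate into a dipeptide (`P_AATL`), cargo
  releases with `P_PLR`; an RNA with bound cargo is folded and protected.
- **Membranes** — amphiphiles above `L_AM` form a membrane
  (`1-(1-P_MF)^(a-L_AM+1)`); amphiphiles join (`P_AJM`) and leave with
  `P_ALM/(y*z)` where `y = 1 + i/(b/2)^(3/2)` (osmotic swelling by inner
  impermeable ions) and `z = 1 + F_MSP*p` (the MSP effect); precursors
  permeate (`P_NPP*(b/L_AM)/y`, `P_APP*(b/L_AM)`, `P_AAPP*(b/L_AM)`);
  protocells move, fuse, break, and divide with
  `P_CD*(1 - 2*L_AM/b)`, assorting their contents randomly.

Only the membrane-stabilizing dipeptide can enter the membrane, so a
protocell whose MSPG gene keeps producing MSP loses fewer amphiphiles,
grows, and divides — protocell-level selection on a molecular-level trait.

## Worked example

Run the reduced-scale spread experiment (ten protocells, each carrying five
MSPG and five control-gene copies, inoculated into a 10 x 10 world):

```bash
drtworld run --scenario fig2a --seed 11 --steps 20000 \
    --set N=10 --set T_NPB=5000 --set T_APB=5000 --set T_AAPB=5000 \
    --out runs/fig2a-reduced
```

which prints

```
finished fig2a: 27 protocells, mspg=28, msp=69 at step 20000
wrote runs/fig2a-reduced/series.csv
```

meaning 27 protocells exist at step 20,000, the system holds 28 copies of
the MSPG gene, and 69 MSP peptides (free + membrane-embedded + RNA-bound).
`series.csv` has one row per 40 steps: protocell class counts (`C_mspg`,
`C_ctpg`, joint classes under `C_other`, `C_empty`, ...), gene copy counts
(`mspg`, `ctpg`, `nsr`, `nspg`, `ctr`), peptide counts (`msp`, `ctp`,
`nsp`) and raw material totals. `drtworld presets` lists the shipped
experiment presets (`fig2a`, `fig2b`, `fig3_<param>_<up|down>`, `fig4a`,
`fig4b`, `fig5a`, `fig5b`, `competition_nsr_vs_nspg`); the takeover
scenarios (`fig4b`, `fig5b`) are full-scale, million-step runs — expect
hours.

As a library:

```python
import drtworld as d

overrides, scenario = d.preset("fig2a", total_steps=20_000,
                               inoculation_step=2_000)
params = d.load_params(None, {**overrides, "N": 10, "T_NPB": 5000,
                              "T_APB": 5000, "T_AAPB": 5000})
world = d.init_world(params, seed=11)
series = d.run(world, scenario)
print(d.audit_conservation(world))   # exact integer ledger identity
```

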