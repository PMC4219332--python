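# fluxdose

Search for multi-drug treatments that modulate one metabolic reaction while
perturbing the rest of the network as little as possible — with *partial*
enzyme inhibition, not just ON/OFF knockouts.

A drug `k` at dosage `h_k ∈ [0,1]` tightens each of its target bounds to
`U_i (1 - h_k)`. The treated flux state is the L1 minimal adjustment
(closest feasible point to the untreated fluxes), and the treatment search

```
min  ‖v_tr(h) − v_ut‖₁ + b·Σ h_k    s.t.  v_mod_tr(h) ≤ τ·v_mod_ut   (or ≥, activation)
```

is a bilevel program: the inner adjustment LP is folded into a single
mixed-integer linear program via LP strong duality (see `docs/duality.md`).
Dosages are discretized through convex combinations of Boolean variables —
a binary expansion on the grid `{m/2^P}`, or measured dose-response levels —
so the problem stays linear. Solved with scipy's HiGHS MILP interface.

## Layout

| module                | contents |
|-----------------------|----------|
| `fluxdose.netio`      | model I/O (structured text, TSV triplets, SBML via cobrapy), canonical all-irreversible form, two-stage reference FBA, synthetic network generator |
| `fluxdose.inhibition` | drug catalogs, Boolean dosage encodings/decoders, bound tightening `W(h)` |
| `fluxdose.moma`       | forward L1 (LP) and L2 (QP) minimal-adjustment solvers, side-effect metric |
| `fluxdose.bilevel`    | the single-level MILP: primal/dual blocks, strong-duality coupling, big-M product linearization, dual-bound estimation, LP/MPS export |
| `fluxdose.analysis`   | exhaustive dosage-grid oracle, nonlinearity index η, two-drug interaction surfaces, all-reactions screening with most-stringent-threshold deduplication |
| `fluxdose.cli`        | `fluxdose` command-line interface |
| `fluxdose.fixtures`   | tiny certified worked examples (`chain`, `diamond`, `superfluous`, `activation`) |

## CLI

```sh
# random toy instance
fluxdose generate --n-metabolites 5 --n-reactions 10 --seed 1 --out-prefix toy

# single solve (config file + flag overrides)
fluxdose optimize --model toy.model --catalog toy.drugs --mod biomass \
    --tau 0.5 -P 2 --outdir out

# independent exhaustive check of the same run
fluxdose oracle --model toy.model --catalog toy.drugs --mod biomass --tau 0.5 -P 2

# screen every reaction over a threshold list
fluxdose screen --model toy.model --catalog toy.drugs --mod biomass \
    --tau-list 0.1 --tau-list 0.5 -P 1 --outdir screen_out

# two-drug interaction surface (17x17 at -P 4)
fluxdose surface --model toy.model --catalog toy.drugs --mod biomass \
    --drug-a drug_0 --drug-b drug_1 -P 4 --norm L1 --norm L2 --outdir surf_out
```

All subcommands also accept `--config run.yaml` with the same keys as the
flags; reports embed the config hash, seed, solver identity and tolerances.

## File formats

The native model dialect is documented in `fluxdose.netio.MODEL_SCHEMA`
(and by the fixture files under `src/fluxdose/data/fixtures/`); drug
catalogs in `fluxdose.inhibition.CATALOG_SCHEMA`. TSV triplet models are a
`<base>.stoich.tsv` (metabolite, reaction, coefficient) plus
`<base>.bounds.tsv` (reaction, reversible, lower, upper, biomass). SBML
needs the optional `cobra` dependency.
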