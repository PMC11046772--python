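# bisdl

A compact text language for describing spatial, multicellular synthetic-biology
designs, together with:

* a **parser/validator** for the indentation-delimited source syntax
  (`bisdl.language_ast`),
* a **nets-within-nets Petri-net engine** — label-multiset markings, net
  tokens, read/inhibitor arcs, synchronous channels, integer timescale
  gating and two-level marking mirroring (`bisdl.nwn_core`),
* a **compiler** lowering a module onto a two-level model: a spatial-grid
  top net hosting one scope net per declared compartment, with diffusion
  and juxtacrine contact wiring across cells (`bisdl.compiler`),
* a **discrete-time stochastic simulator** with periodic stimulus schedules
  and CSV trace recording (`bisdl.simulator`),
* programmatic **case-study fixtures**: a water-formation toy reaction, a
  two-cell bacterial consortium (LacI-controlled AHL/GFP signalling), a 5×5
  RGB synthetic-morphogen patterning grid, and a conjugative plasmid
  transfer chain (`bisdl.examples_fixtures`),
* a **CLI** (`bisdl compile / simulate / fixtures`).

## Language at a glance

```text
MODULE waterReaction
    TIMESCALE 1
    SCOPE s(0, 0)
        MARKING(4*H2_molecule, 2*O2_molecule)
        PROCESS reaction
            TIMESCALE 1
            CUSTOM_PROCESS(2*H2_molecule + O2_molecule -> 2*H2O_molecule)
```

Scopes sit at 2-D grid coordinates; processes bundle constructs
(`TRANSCRIPTION`, `TRANSLATION`, `DEGRADATION`, `PROTEIN_COMPLEX_FORMATION`,
`ENZYMATIC_REACTION`, `CUSTOM_PROCESS`) with optional `INDUCERS` /
`ACTIVATORS` / `INHIBITORS` role clauses; entity base types derive from name
suffixes (`_gene`, `_mRNA`, `_protein`, `_complex`, `_molecule`).
`DIFFUSION(entity, a <-> b)` moves tokens between grid cells;
`JUXTACRINE_SIGNAL(emit|receive, entity, partner)` pairs into synchronous
contact channels between adjacent cells.  A process timescale multiplies the
module pace: a transition at effective pace `T` is visited every `T`-th tick,
firing with probability `p` (default 0.6).  See `docs/grammar.md` for an
EBNF sketch.

## CLI

```sh
bisdl fixtures -o fixtures/                       # write bundled case studies
bisdl compile fixtures/bacterial_consortium/bacterial_consortium.bisdl -o out/
bisdl simulate fixtures/bacterial_consortium/bacterial_consortium.bisdl \
      -c fixtures/bacterial_consortium/highLacI.yaml -o run/ --seed 7
```

`compile` writes a JSON model manifest plus one Graphviz DOT file per net;
`simulate` writes `trace.csv` (`tick,scope,place,count`), `events.csv` and a
run manifest with input digests.  Runs are bit-reproducible for a given seed.

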