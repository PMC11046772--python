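# Source-syntax sketch (EBNF)

Blocks are delimited by indentation (spaces only); `#` starts a comment
running to end of line; blank lines are ignored.

```ebnf
module      = "MODULE" ident NEWLINE INDENT module_item* DEDENT ;
module_item = timescale | scope | diffusion ;
timescale   = "TIMESCALE" integer NEWLINE ;

scope       = "SCOPE" ident "(" integer "," integer ")" NEWLINE
              INDENT scope_item* DEDENT ;
scope_item  = marking | process | signal ;
marking     = "MARKING" "(" term { "," term } ")" NEWLINE ;

process     = "PROCESS" ident NEWLINE [ INDENT timescale construct* DEDENT ] ;
              (* a PROCESS with no body reuses the definition with the same id *)

construct   = kind "(" args ")" NEWLINE ;
kind        = "TRANSCRIPTION" | "TRANSLATION" | "DEGRADATION"
            | "PROTEIN_COMPLEX_FORMATION" | "ENZYMATIC_REACTION"
            | "CUSTOM_PROCESS" ;
args        = positional { "," positional } { "," role_clause } ;
positional  = term | term_sum | arrow ;
term_sum    = term { "+" term } ;
arrow       = [ term_sum ] "->" [ term_sum ] ;
role_clause = ( "INDUCERS" | "INHIBITORS" | "ACTIVATORS" )
              "(" term { "," term } ")" ;
term        = [ integer "*" ] ident ;          (* multiplier defaults to 1 *)

signal      = "PARACRINE_SIGNAL" "(" dir "," ident ")" NEWLINE
            | "JUXTACRINE_SIGNAL" "(" dir "," ident "," ident ")" NEWLINE ;
dir         = "emit" | "receive" ;

diffusion   = "DIFFUSION" "(" ident "," endpoints ")" NEWLINE ;
endpoints   = ident "<->" ident | ident "->" ident | "all" ;
```

Positional-argument meaning by construct kind:

| kind                        | positionals                                  |
|-----------------------------|----------------------------------------------|
| `TRANSCRIPTION`             | template gene (read), product mRNA           |
| `TRANSLATION`               | template mRNA (read), product protein        |
| `DEGRADATION`               | one consumed term                            |
| `PROTEIN_COMPLEX_FORMATION` | components… (consumed), product (last)       |
| `ENZYMATIC_REACTION`        | enzyme (read), `substrates -> products`      |
| `CUSTOM_PROCESS`            | `inputs -> outputs` (either side may be empty) |

Entity base types come from the name suffix: `_gene`, `_mRNA`, `_protein`,
`_complex`, `_molecule` (anything else defaults to molecule).
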