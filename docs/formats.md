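# File formats

All artifacts are plain tab-separated text except the reaction database,
which uses a small stanza format defined below.

## Feature tables (`otu_table.tsv`, `ec_table.tsv`)

First column = feature id (header `feature_id`), remaining columns = sample
ids; values are non-negative. A `counts` table holds integers; a
`proportions` table has every sample column summing to 100.

## Sample metadata (`metadata.tsv`)

Named columns: `sample_id`, `exceeds_epa_bm` (0/1/true/false, never
missing), `tph` (μg kg⁻¹), `din`, `nh3_n`, `no3_n` (mg l⁻¹), `total_n`
(mass fraction), `distance_km`, `depth_m`. Missing values are written `NA`.
Unknown columns are ignored with a warning.

## Hit tables (`hits/<sample>.tsv`)

12-column BLAST `outfmt 6`: query, subject, %identity, alignment length,
mismatches, gap opens, qstart, qend, sstart, send, e-value, bit score.
Columns 5–10 are parsed for arity but unused.

## Hierarchy map (`hierarchy.tsv`)

4 columns with header: `function_id`, `level1`, `level2`, `level3`. The map
must be total over the features queried.

## Reaction database (`reactions.txt`)

One reaction per stanza; stanzas separated by `//` or blank lines; `#`
starts a comment line.

```ebnf
database  = { stanza } ;
stanza    = id-line ec-line eq-line terminator ;
id-line   = "ID" SP identifier NL ;
ec-line   = "EC" SP ec-number { ";" SP ec-number } NL ;
eq-line   = "EQ" SP side SP arrow SP side NL ;
arrow     = "=>" | "<=>" ;            (* "<=>" marks a reversible reaction *)
side      = term { SP "+" SP term } ;
term      = [ coefficient SP ] metabolite-id ;
coefficient = digits [ "." digits ] ; (* omitted coefficient = 1 *)
ec-number = digits "." digits "." digits "." ( digits | "-" ) ;
terminator = "//" NL | blank-line ;
```

The left side is taken as consumed (substrates), the right as produced, as
written. A metabolite may appear at most once per side; substrate and
product lists must be non-empty and every stanza needs at least one EC.

Example:

```
ID R_nar
EC 1.7.5.1
EQ NO3- => NO2- + H2O
//
```
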