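# rmdefrag

Defragment RepeatMasker `.out` annotations into transposable-element (TE)
copies, reconstruct LTR-retrotransposons and solo-LTRs, and quantify repeat
content per family and per query sequence.

## The problem

RepeatMasker reports one line per alignment between a library consensus and
the query ("hit"), but a hit is not a TE copy. A single insertion is routinely
split across several hits:

* repeat libraries store an LTR-retrotransposon as two consensi — the long
  terminal repeat (`FOO_LTR`) and the internal portion (`FOO_I`) — so one
  full-length element yields at least three hits (LTR, internal, LTR);
* large deletions break an old copy into collinear fragments with a gap in
  consensus coordinates;
* a TE nested inside another splits the host copy in two.

Any per-family analysis (copy number, insertion-age proxies such as
divergence, solo-LTR/full-length ratios) needs the *copies*, not the hits.
`rmdefrag` is a post-processor that recovers them.

## The method

Two hits of the same family on the same query sequence are fragments of one
copy when

1. they have the same orientation;
2. their furthest extremities span less than `2 × L_ref`, the reference
   (consensus) length of the element — or, with `--insert s`, the sequence
   between their closest extremities is `≤ s` bp;
3. the second fragment starts and ends strictly after the first starts and
   ends (overlap allowed, containment not).

Chaining is greedy along the query. When several open chains can accept a
fragment, solution 0 merges the closest hits; RepeatMasker block IDs resolve
a case unequivocally when they agree, and `--choice` delegates to the user.

For LTR families the two portions are chained separately (a fragment of the
other portion inside the gap blocks a merge), then LTR copies are paired
with internal copies that are on the same strand and separated by a gap
`< L_LTR / 2`. Full `LTR-I-LTR` elements are assembled first, then partial
`LTR-I` / `I-LTR`; remaining lone LTR copies are solo-LTRs.

Per copy the tool reports size-weighted means of `%_Div`, `%_Del`, `%_Ins`
(weights = fragment query spans) and the length ratio

    %_of_Ref = Σ fragment consensus spans / reference length,

where the denominator is `L_I + 2·L_LTR` for `LTR-I-LTR`, `L_I + L_LTR` for
partial elements, and `L_LTR` for solo-LTRs (a full-length solo-LTR has
ratio 1.00). `--strict` applies the size and identity parts of the 80-80-80
rule: keep copies > 80 bp (consensus-aligned) with > 80 % identity.

Reference lengths are taken from every hit (`r_end + r_left`), keeping the
modal value per element, or from a user `.length` file (which also restricts
the analysis to the elements it lists).

## Worked example

Generate a bundled fixture — an LTR-retrotransposon (*Quasimodo*-like)
interrupted by a reverse-orientation, internally deleted DNA transposon
(*hobo*-like), six hits in total — and run the two stages:

```sh
python -c "from rmdefrag.synthetic import make_scenario;
open('sim.fa.out','w').write(make_scenario('nested').out_text)"
rmdefrag build-dictionary --rm sim.fa.out > dict.txt
rmdefrag assemble --rm sim.fa.out --ltr dict.txt
```

The terminal (and `sim.fa.out.log.txt`) shows:

```
Parsed 6 hits on 1 query sequence(s)
Assembled 2 copies from 6 TE hits (0 hits outside copy assembly)
Element HOBO (DNA/hAT): 2 hits, 1 copies
Element QUASIMODO (LTR/Gypsy): 4 hits, 1 copies, 0 solo-LTR(s)
Ambiguous situations: 0
```

Six hits, two biological copies. `sim.fa.out.copynumber.csv` quantifies each
element (fragments, copies, solo-LTRs, base pairs, percent coverage of the
query):

```
Family     Element    Length  Fragments  Copies  Solo_LTR  Total_Bp  Cover
DNA/hAT    HOBO       3016    2          1       NA        2800      9.33
LTR/Gypsy  QUASIMODO  3600    4          1       0         3600      12.00
```

and `sim.fa.out.ltr.csv` lists the reconstructed LTR element — a copy line
(`###` + merged block IDs) followed by its four fragments:

```
###5/5/5/5  5.00  1.00  0.50  chr_sim  1001  7500  3600  +  QUASIMODO  LTR/Gypsy ...  4  1.00
1500        5.00  1.00  0.50  chr_sim  1001  1300   300  +  QUASIMODO_LTR ...
4000        5.00  1.00  0.50  chr_sim  1301  2800  1500  +  QUASIMODO_I ...
4000        5.00  1.00  0.50  chr_sim  5701  7200  1500  +  QUASIMODO_I ...
1500        5.00  1.00  0.50  chr_sim  7201  7500   300  +  QUASIMODO_LTR ...
```

The copy spans 1001–7500 on the `+` strand, its consensus-view length is
3600 bp and `%_of_Ref` is 1.00: a full-length element. `*.transposons.csv`
holds the non-LTR copies and `*.elem_sorted.csv` merges both in genomic
order. Add `--fasta sim.fa` (optionally `--flanking N`) to write each copy's
sequence.

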