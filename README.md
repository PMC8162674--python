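# cleavspec

Protease cleavage-specificity profiling: from phage-display-selected
peptides and substrate-assay readouts to position-specific cleavage models,
primary-specificity calls, and consensus-driven proteome screening for
candidate in vivo cleavage targets.

The package is written for researchers characterizing serine-protease
specificity with substrate phage display — the setting in which the
ruminant/pig intestinal duodenases were profiled: a T7 phage library
displays random nonamers in the fixed capsid context `PGG(X)9HHHHHH`,
His-tag capture anchors the phages on a Ni-NTA matrix, and proteolytic
cleavage inside the insert releases them. After 5–7 rounds of selection,
sequencing ~60–96 clones yields nonamers enriched for cleavable sequences —
but not the position of the scissile bond within each of them.

## The model

Substrate residues are numbered in Schechter–Berger notation: P4…P1 on the
N-terminal side of the scissile bond, P1′…P3′ on the C-terminal side;
cleavage occurs between P1 and P1′. For each selected nonamer the cleavage
*register* (which insert residue was P1) is latent. `cleavspec` treats this
as one-site-per-sequence motif inference:

- each peptide's P4…P3′ window is drawn from a position frequency matrix
  (PFM) *f*, all other insert residues from background *b*;
- the register posterior is ∝ the window log-odds Σ log(*f*/*b*), summed
  over window positions that fall inside the randomized insert (residues
  read from the fixed capsid flanks are known constants and carry no
  register information);
- expectation-maximization with multi-start re-estimates *f* and the
  registers jointly; an exhaustive oracle certifies the optimum on small
  instances.

A coherent shift of every register is a near-exact symmetry of this
likelihood whenever the informative motif is narrower than the window, so
the absolute P1 placement is not identifiable from phage inserts alone —
exactly as on the bench, where chromogenic substrate assays, not phage
display, ultimately place the scissile bond. The aligner therefore accepts
a `p1_anchor` (the P1 residue class called from a substrate panel) to pin
the register gauge, and falls back to centring the cleavage positions in
the insert.

From the aligned windows the package derives the log-odds weight matrix
(PWM, log2 *f*/*b*), per-position information content (Kullback–Leibler
divergence from background, bits), a degenerate consensus pattern with
hard-required positions and forbidden residue classes near P1 (serialized
as e.g. `P4:[FWY] P3:D P2:. P1:D! … ; forbid[DE]±3 ; mm<=1`), and a
primary-specificity call (tryptase / chymase / asp-ase / elastase / dual /
undetermined) from the P1 column. Proteins are then scanned — PWM score
threshold or pattern mismatch budget — to nominate candidate in vivo
cleavage sites. A synthetic-data module generates every input the pipeline
consumes (planted specificity models, biopanning dynamics, planted-site
proteomes, noisy assay series), so the whole analysis is testable without
downloads.

## Worked example

Simulate a biopanning of the Asp-ase archetype (prefers Asp at P1 and P3
with an aromatic P4), profile the sequenced clones, and screen a synthetic
proteome with the resulting consensus:

```
$ cleavspec simulate panning --truth aspase --seed 0 --out-dir panning
$ cut -f1-5 panning/rounds.tsv
round  released_enzyme  released_control  enrichment_fold  top_clone_fraction
1      150              83                1.80723          0.00666667
2      10091            112               90.0982          0.0198196
3      24974            100               249.74           0.0215424
4      25220            91                277.143          0.0212133
5      24613            105               234.41           0.0217771
```

Release with enzyme starts near the spontaneous-release control (fold ≈ 2)
and climbs above 200-fold by round 3 as cleavable clones take over the
amplified pool.

```
$ cleavspec profile panning/sequenced.txt --dialect delimited \
      --p1-anchor DE --out-dir profile
$ cat profile/consensus.txt
P4:[FWY] P3:D P2:. P1:D! P1':. P2':. P3':. ; mm<=0
$ python -c "import json; d = json.load(open('profile/call.json')); \
             print(d['label'], {k: round(v, 3) for k, v in d['evidence'].items()})"
asp-ase {'asp-ase': 0.915, 'chymase': 0.014, 'elastase': 0.019, 'tryptase': 0.009}
```

The 96 sequenced clones align into a consensus requiring Asp at P1 and P3
with an aromatic P4 — the planted enzyme's signature. Per-position
information (bits): `[2.09, 3.51, 0.37, 3.51, 0.40, 0.61, 1.00]` for
P4…P3′: the three preference-carrying positions stand out. The `--p1-anchor
DE` flag passes the P1 class the chromogenic panel would report (`cleavspec
assay` computes it from an absorbance table); without an anchor the
register gauge is set by centring and may sit one position off.

```
$ cleavspec simulate proteome --truth aspase --n-proteins 40 --n-plants 4 \
      --seed 1 --out-dir proteome
$ cleavspec scan "$(cat profile/consensus.txt)" proteome/proteome.fasta --out-dir scan
$ head -3 scan/hits.tsv
protein_id  start  end  p1_position  window    score  mismatches
synprot1    45     52   50           TGFDADAA         0
synprot2    58     65   63           WNFDADAA         0
```

All four planted sites are recovered at their recorded coordinates
(1-based, inclusive; the reported octamer spans P6…P2′), alongside three
accidental background matches that the planting registry also records.

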