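# cldkit

Structural analysis of **causal loop diagrams** (CLDs) — the signed
directed graphs used in system dynamics to map how a complex problem,
such as the vicious cycle of sleep disturbance and depressive symptoms in
young adults, sustains itself through feedback.

A CLD connects system variables (each assigned to one biopsychosocial
domain: biological, psychological, behavioral or social) by causal
connections with polarity `+` (target moves with the source), `−`
(opposite direction) or `ambiguous`. Its feedback loops are directed
simple cycles, classified by the parity rule

> a loop with an odd number of negative connections is **balancing**
> (self-correcting); an even number makes it **reinforcing**
> (amplifying),

and by scale: **within-scale** when all member variables share one
domain, **cross-scale** otherwise. cldkit is for modelers who build such
diagrams from multi-expert elicitation and need the quantitative steps of
that workflow to be reproducible:

- **`cldkit.core` / `cldkit.io`** — validated diagram model (unique ids,
  resolving endpoints, one connection per ordered pair, no self-loops by
  default); native JSON and GraphML with lossless round-trips, CSV edge
  lists, DOT export; summary counts and the derived exogenous set.
- **`cldkit.loops`** — exact enumeration of all feedback loops up to a
  length cap (bounded Johnson-style depth-first search, streaming,
  deterministic order), reinforcing/balancing/undetermined and
  within/cross-scale classification, per-variable loop-participation
  tables with a ranking-stabilization diagnostic, focal-pair queries
  (third parties in triads, bidirectional partners), and validation of
  balancing-loop overlays.
- **`cldkit.harmonize`** — merging free-text variable proposals from
  multiple experts: stopword-aware normalization, mean-of-word-vector
  embeddings behind a pluggable provider contract, cosine pair flagging
  (default > 0.8), average-linkage agglomerative clustering cut at a
  similarity threshold (default 0.58, selectable by the kneedle
  knee-point rule), and the summed importance-rating inclusion cutoff.
- **`cldkit.audit`** — the three-way mediation rule for proposed direct
  connections: retain when some named mechanism is not a diagram
  variable, replace with an indirect path when all mechanisms already
  are, remove when none was identified.
- **`cldkit.synth`** — seeded random diagrams matching a requested
  composition exactly (defaults: 29 variables, 175 connections, 58
  negative, 2 ambiguous, 3 exogenous, domains 5/7/9/8), planted-synonym
  elicitation datasets with ground truth, the printed-figure fixture
  sub-diagrams, and a brute-force loop oracle for verification.

## Worked example

```python
import cldkit as ck

triad = ck.published_fixtures()["smoking_triad"]   # sleep / depressive-symptoms / smoking triad
loops = ck.enumerate_loops(triad, ck.LoopConfig(min_length=2, max_length=3))
for loop in loops:
    print(loop.length, "->".join(loop.sequence), loop.polarity_class)

pair = ("sleep-disturbance", "affective-symptoms-of-depression")
print(ck.third_parties(triad, pair), ck.bidirectional_partners(triad, pair))
print(ck.participation_table(triad, ck.LoopConfig(max_length=3)).table)
```

prints

```
2 affective-symptoms-of-depression->sleep-disturbance reinforcing
2 affective-symptoms-of-depression->smoking reinforcing
2 sleep-disturbance->smoking reinforcing
3 affective-symptoms-of-depression->sleep-disturbance->smoking reinforcing
3 affective-symptoms-of-depression->smoking->sleep-disturbance reinforcing
{'smoking'} {'smoking'}
                           variable  loop_count  percentage
0  affective-symptoms-of-depression           4        80.0
1                 sleep-disturbance           4        80.0
2                           smoking           4        80.0
```

The fully bidirectional triad carries five feedback loops (three of
length 2, two of length 3), all reinforcing — every pathway amplifies the
others, which is what makes the smoking/sleep/mood entanglement a
candidate vicious cycle. `smoking` is the unique third variable closing
length-3 loops with the focal pair, and it does so in both cyclic
orientations. Each variable sits on 4 of the 5 loops, hence the 80.0%
participation.

The same analyses run from the shell:

```sh
cldkit synth cld --seed 3 --out d.json      # published-diagram-shaped random diagram
cldkit loops count --cld d.json --min 2 --max 5
cldkit loops rank  --cld d.json --max 5 --top 10
cldkit loops triads --cld d.json --pair v03-psyc,v12-beha
cldkit harmonize --proposals proposals.csv --cluster-threshold 0.58
cldkit audit --cld d.json --edge v03-psyc,v12-beha --mechanisms "stress;diet"
```

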