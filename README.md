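# pathviz

Scriptable pathway analysis for omics data: build and edit GPML pathway
diagrams, map dataset identifiers onto pathway nodes, paint colour
gradients and rules onto the nodes, rank pathways by a hypergeometric
Z score, and export everything as a navigable, hyperlinked HTML report.
The same surface is reachable three ways — as a Python library, as the
`pathviz` command line tool, and as an XML-RPC server exposing
`PathVisio.*` methods — so the pathway step can sit directly inside the
R/Python/Perl scripts that did the upstream normalisation and
differential-expression work, instead of a desktop GUI.

It is aimed at bioinformaticians who have a gene-level (or protein- or
metabolite-level) statistics table and a collection of pathway diagrams,
and want repeated, reproducible over-representation analysis and data
visualisation without clicking through an interactive application.

## The statistic

For each pathway, with

* **N** — distinct measured genes in the dataset (after identifier
  unification; rows that cannot be mapped at all are excluded),
* **R** — genes meeting the user criterion (e.g. `[P.Value] < 0.05`),
* **n** — measured genes linked to the pathway,
* **r** — of those, the ones meeting the criterion,

the pathway's score is the standardised over-representation Z score

```
        r − n·R/N
Z = ──────────────────────────────────────────
    sqrt( n·(R/N)·(1 − R/N)·(1 − (n−1)/(N−1)) )
```

i.e. the observed hit count minus its expectation under random draws of
n genes from the N measured ones, divided by the exact hypergeometric
standard deviation (finite-population correction included). Z > 0 means
the pathway holds more changed genes than the dataset-wide rate
predicts; Z < 0 fewer; Z is undefined (reported `NaN`) when the variance
is zero. No multiple-testing correction is applied — the result is the
ranked list of raw Z scores.

## Worked example

The package ships a deterministic fixture generator that emulates a
differential-expression results table (1000 mouse-style genes with
logFC and P-value columns for three time points), a two-system
identifier mapping, and ten 30-gene pathways of which the first is
enriched threefold over the 20 % background hit rate:

```python
from pathviz import FixtureSpec, make_fixture
make_fixture(FixtureSpec(seed=11), "demo")
```

```sh
pathviz analyze --data demo/data.tsv --id-column GeneID --syscode SystemCode \
  --pathways demo/pathways --mapping demo/mapping.tsv \
  --criterion "[P.Value_d1] < 0.05" \
  --gradient "logFC_d1:blue@-1,white@0,red@1" \
  --rule "P.Value_d1:[P.Value_d1] <= 0.05 -> green" \
  --out demo/results
```

prints

```
scored 10 pathways (N=950, R=193); top: Fixture pathway 00 (z=5.487)
results table: demo/results/results.tsv
report: demo/results/html/index.html
```

N=950 because 5 % of rows are deliberately unmappable and drop out of
the universe; R=193 genes pass the P < 0.05 criterion; the planted
pathway tops the ranking at Z ≈ 5.5 (18 of its 30 genes hit versus the
≈6 expected). `results.tsv` holds one row per pathway
(`pathway  file  n  r  N  R  z`), and `html/index.html` is the
self-contained report: settings overview, the clickable Z-ranked
pathway list, the legend, and per-pathway pages whose PNG image maps
link every node to a back page with its annotation, database links and
matched measurements.

The same run over XML-RPC:

```python
from xmlrpc.client import ServerProxy
from pathviz import start_server

handle = start_server()          # binds 127.0.0.1:7777
proxy = ServerProxy(handle.url)
doc = getattr(proxy, "PathVisio.createPathway")("Glycolysis")
getattr(proxy, "PathVisio.addDataNode")(doc, "Fos", "GeneProduct", "14281", "L")
```

Batch processing of many files with per-file settings uses an INI
config (`pathviz batch config.ini`); see `docs/example-batch.ini` and
`pathviz batch --help` for the grammar.

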