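# Methods

## Overview

pathviz implements the post-statistics stage of a pathway analysis
workflow: a table of per-gene (or per-protein/metabolite) statistics is
linked to a collection of pathway diagrams through identifier mapping,
each pathway is scored for over-representation of criterion-meeting
genes, the data are painted onto the diagrams, and the whole result is
exported as a hyperlinked HTML report. This note records the models,
conventions and open design choices behind each stage.

## Pathway documents and the GPML dialect

Documents are diagrams of typed data nodes (GeneProduct, Protein,
Metabolite, Rna, Pathway, Unknown), free text labels, and directed
interactions (line, arrow, t-bar, conversion, catalysis). Geometry is
centre-based in abstract diagram units with y increasing downward, the
GPML convention. Default node size is 80×20 units, a typical GPML
datanode extent. Nodes added without coordinates fall into an
auto-layout grid (rows of 10, 100×40-unit pitch) so that pathways built
from bare gene lists are immediately renderable.

Files are read and written in a GPML-2013a-like subset: a `Pathway`
root with `Name`/`Organism` attributes, a `Graphics` child with board
extents, `DataNode`/`Label`/`Interaction` children with `Graphics` and
`Xref` children. Two deliberate deviations from stock GPML-2013a:

* **No xmlns on the root.** Unknown root children are preserved as
  opaque blobs and re-emitted verbatim so third-party extensions
  survive a round trip; a default namespace would force the serialiser
  to inject `xmlns` attributes into those blobs and break both the
  verbatim guarantee and byte-stable re-writes. The reader still
  accepts namespaced input (real GPML-2013a files parse fine).
* **`Xref/@Database`** holds the full datasource name for registered
  system codes (e.g. "Entrez Gene" for `L`) and the raw string
  otherwise, mapped back to a code on read, so unregistered codes
  round-trip unchanged.

The writer emits elements in document order with canonical float
formatting, so identical documents always produce identical bytes;
write→read→write is byte-stable. Interactions that reference removed
elements are kept and flagged `dangling` rather than silently deleted —
scripted edits should not lose edges behind the caller's back.
Schema validation against the official XSD, groups, anchors and curved
connectors are out of scope.

## Identifier mapping

Cross-references are treated as an equivalence web: the pairwise links
of the mapping TSV are closed transitively at load time (union–find),
so any member of a set maps to any other regardless of which pairs were
listed. Identifiers are case-sensitive, as database accessions
generally are. Identity mapping (`source == target`) returns the input
identifier whether or not it occurs in the store, so single-system
datasets work without a mapping file covering every row. System codes
follow the published BridgeDb short codes (`L` Entrez Gene, `En`
Ensembl, `Ce` ChEBI, `Ca` CAS, …) and are user-extensible via
`register_system_code`. Mapping tables are flat TSVs rather than
binary mapping-database archives, keeping the package download-free.

## Measurement tables and the criterion language

Delimited files are sniffed from the header line (tab preferred, comma
fallback; decimal point only). Cells parse to floats where possible;
unparseable cells are retained as text; empty cells and `NA`-style
markers become MISSING. Duplicate identifiers remain distinct rows —
probe averaging is an upstream concern.

Criteria use the bracketed-column dialect, e.g.
`[P.Value] < 0.05 AND [logFC] > 1`, with precedence
NOT > comparison > AND > OR and parentheses. Evaluation is three-valued
(strong Kleene): a comparison touching a MISSING cell is MISSING;
`AND(false, missing) = false`, `OR(true, missing) = true`, otherwise
MISSING propagates. At every counting boundary — Z-score counts and
colour rules — MISSING collapses to "criterion not met": a gene with a
missing statistic is measured (counts toward N) but not changed (does
not count toward R), which keeps the universe stable without inflating
the hit count.

## Linking and multi-mapping

A row matches a node when the mapper connects the row's (system code,
identifier) to the node's xref. One row may colour several nodes. A
node matched by several rows displays the **first matching row in file
order** on the diagram; its back page lists all matching rows and flags
the multiplicity. Linking is deterministic and invariant to row and
node order.

## The Z score

With N measured genes, R criterion hits, n pathway genes and r pathway
hits, the score is

    z = (r − n·R/N) / sqrt( n·(R/N)·(1−R/N)·(1−(n−1)/(N−1)) )

— the observed hit count standardised by the mean and variance of the
hypergeometric distribution of r under random sampling of n genes from
N without replacement (the last factor is the finite-population
correction). The statistic is defined in words in the
over-representation literature this follows; the hypergeometric
variance is the standard reading and is verified in the test suite
against an exact enumeration of the pmf and a Monte-Carlo oracle.
z is undefined when the variance vanishes (n = 0, R = 0, R = N or
n = N) and is reported as `NaN`, sorted after all defined scores; ties
break by pathway name ascending.

Counting runs over **unified gene identities**: each row is mapped into
one unification system (by default the collection's most frequent xref
system, ties alphabetical) and keyed by the smallest image, so
duplicate probes count once; a gene is "in a pathway" when its image
set intersects the pathway's node images; a gene is a hit when any of
its rows meets the criterion. Rows with no image in the unification
system are excluded from N — they can never hit a pathway — and the
excluded count is echoed in the results. N is dataset-wide, not
restricted to genes occurring in some pathway. No multiple-testing
correction is applied; consumers needing FDR control must apply it to
the exported table themselves. This is a documented limitation.

## Visualisation

Per visualised column, either a gradient (2–3 anchors of
(value, colour), strictly increasing values) or an ordered rule list.
Gradient interpolation is piecewise-linear per RGB channel between the
bracketing anchors, clamped to the end anchors outside the range, with
round-half-up to integer channels. Rules fire first-true-wins;
MISSING falls through; the fallback is white (255,255,255).

A mapped node is divided into k equal-width **vertical** stripes, one
per spec entry, left to right in spec order; stripe pixel edges are
`round(i·w/k)` so widths sum exactly to the node width with no overlap.
Nodes with no matching row are solid light grey (211,211,211), as is a
missing cell inside a mapped node. Rasterisation is fixed at 2 px per
diagram unit; hit regions are reported in raster pixels for the HTML
image maps. Labels are drawn centred without font-metric guarantees —
tests assert geometry and colours, not glyphs. SVG output is built as
deterministic text, so identical inputs give identical bytes.

## HTML report

Layout: `index.html` (settings, Z-ranked clickable list, legend, and a
content iframe standing in for the classic frameset), `pathways/<slug>.html`
with the embedded PNG and a `<map>` of one `<area shape="rect">` per
data node, `backpages/<slug>/<element_id>.html`, and `assets/`. Slugs
are sanitised pathway names with `-2`, `-3` collision suffixes. Back
pages render the node annotation — with configurable database URL
templates per system code (Entrez and Ensembl patterns shipped;
missing template → plain text) — and every matched measurement row,
or an explicit "no data" statement. The settings block prints the
criterion, N, R, the collection size and the excluded-row count; no
timestamps, so re-export over an existing directory is byte-idempotent.

## RPC service and CLI

The XML-RPC server (default port 7777, loopback bind unless widened
explicitly) exposes the library surface under `PathVisio.*` method
names. Documents, tables and mapping stores travel as opaque string
handles in a per-server session store; handles expire on stop, and a
restarted server starts empty. Domain errors become XML-RPC faults
(code 1 unknown method, 2 bad arguments, 3 domain error). The
`dispatch` function implements the same routing without a socket and is
what the equivalence tests drive.

The CLI (`pathviz serve | analyze | batch`) is a thin layer over the
same pipeline. Batch configs are INI files, one section per data file,
with a small line grammar for gradients and rules (see
`docs/example-batch.ini`); entries run independently, a failed entry is
logged and skipped, and the exit code is non-zero if any entry failed.

## Synthetic data generator

`make_fixture` emulates the shape of a multi-timepoint
differential-expression result for a mouse-style experiment: one row
per gene with Entrez-like numeric identifiers, three logFC and three
P-value columns by default, a disjoint pathway collection whose nodes
carry Ensembl-like identifiers, and a two-system mapping TSV with a
known bijection. Defaults: 1000 genes, 10 pathways × 30 genes, 20 %
background criterion-hit rate with the first pathway planted at 60 %
(threefold enrichment), 5 % unmappable rows, no missing cells. Hits
are drawn Bernoulli per gene and encoded exactly in the first P-value
column (0.01 hit / 0.5 non-hit), so `[P.Value_d1] < 0.05` recovers the
planted truth; the truth record stores exact (N, R, n, r) per pathway
from the generator's own bookkeeping, independent of the counting code
it tests. All output is a deterministic function of the seed.

What the generator does **not** emulate: realistic expression or
P-value distributions, correlated genes, overlapping pathways,
many-to-many identifier webs, probe-level duplication, or annotation
errors. Passing tests therefore demonstrate the correctness of the
counting, scoring, rendering and export machinery under clean planted
structure — not robustness to the messiness of real curated pathway
collections or real array data.

## Problem sizes used in the checks

The enumeration check covers every valid (N, R, n, r) with N ≤ 20
(10 625 tuples) exactly, plus 20 random larger configurations against
100 000 hypergeometric draws each. Planted-enrichment recovery uses
200 generated datasets at the default conditions (N = 1000, n = 30,
3× enrichment, unmappable fraction zero so the universe is exactly
1000). Round-trip stability uses 500 random documents; criterion logic
200 random expressions × all 81 assignments of {0, 1, missing} to four
columns; gradient interpolation 1000 random gradients. These sizes are
the package's documented reference conditions and complete in seconds.

## Known limitations

* Raw Z scores only; no p-values or FDR.
* One row shown per node on the diagram (full list on the back page).
* Straight-line interaction rendering; no anchors, groups or curves.
* The RPC layer is single-session: all clients share one handle store.
* The criterion grammar has no arithmetic: operands are columns and
  literals only (column-vs-column comparisons work, `[a] + 1` does
  not).
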