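"""Deterministic generators for toy pathways, mapping tables and measurement
tables with planted statistical structure.

The generator emulates the shape of a gene-level differential-expression
results table (mouse-style numeric gene ids, logFC and P-value columns per
time point) together with a small pathway collection and a two-system
identifier mapping, so every pipeline stage — GPML IO, identifier mapping,
linking, criterion evaluation, Z scores, rendering, HTML export — can be
exercised offline with known ground truth.

Structure planted per seed:

* two identifier systems with a known bijection: Entrez-like ids ("L") used
  by the measurement table and Ensembl-like ids ("En") used by pathway
  nodes, plus a configurable fraction of unmappable rows;
* per-gene criterion hits drawn Bernoulli at ``background_hit_rate``,
  except genes of pathway 0 which use ``enriched_pathway_rate``;
* the criterion column is set to 0.01 for hits and 0.5 for non-hits so
  that ``[P.Value_d1] < 0.05`` recovers the planted truth exactly.

The truth record stores the exact (N, R, n, r) per pathway computed from
the generator's own bookkeeping, independent of the counting code it is
used to test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import PathwayDoc, Xref, add_data_node, create_pathway, write_gpml

__all__ = ["FixtureSpec", "FixtureResult", "make_fixture", "CRITERION_TEXT"]

CRITERION_TEXT = "[P.Value_d1] < 0.05"


class FixtureError(Exception):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters; all randomness is determined by ``seed``."""

    seed: int = 0
    n_genes: int = 1000
    n_pathways: int = 10
    genes_per_pathway: int = 30
    background_hit_rate: float = 0.2
    enriched_pathway_rate: float = 0.6   # 3x background: the planted signal
    n_value_columns: int = 6             # half logFC, half P-value columns
    missing_rate: float = 0.0
    unmappable_fraction: float = 0.05
    organism: str = "Mus musculus"

    def __post_init__(self):
        probs = (
            self.background_hit_rate,
            self.enriched_pathway_rate,
            self.missing_rate,
            self.unmappable_fraction,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise FixtureError("rates must lie in [0, 1]")
        if min(self.n_genes, self.n_pathways, self.genes_per_pathway, self.n_value_columns) <= 0:
            raise FixtureError("counts must be positive")
        if self.genes_per_pathway > self.n_genes:
            raise FixtureError("genes_per_pathway cannot exceed n_genes")


@dataclass
class FixtureResult:
    pathway_dir: Path
    pathway_files: list[Path]
    mapping_path: Path
    data_path: Path
    truth_path: Path
    truth: dict


def _entrez_like(i: int) -> str:
    return str(100001 + i)


def _ensembl_like(i: int) -> str:
    return f"ENSMUSG{i:011d}"


def make_fixture(spec: FixtureSpec, out_dir) -> FixtureResult:
    """Generate the fixture bundle under ``out_dir``.

    Writes ``pathways/pw_XX.gpml``, ``mapping.tsv``, ``data.tsv`` and
    ``truth.json``; byte-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    pathway_dir = out_dir / "pathways"
    pathway_dir.mkdir(parents=True, exist_ok=True)

    n = spec.n_genes
    entrez = [_entrez_like(i) for i in range(n)]
    ensembl = [_ensembl_like(i) for i in range(n)]

    # unmappable genes are drawn outside any pathway so they can never hit one
    n_unmappable = int(round(spec.unmappable_fraction * n))
    need = spec.n_pathways * spec.genes_per_pathway
    if need > n - n_unmappable:
        raise FixtureError(
            f"{spec.n_pathways} disjoint pathways x {spec.genes_per_pathway} genes "
            f"need {need} mappable genes; only {n - n_unmappable} available"
        )
    perm = rng.permutation(n)
    unmappable = set(perm[:n_unmappable].tolist())
    mappable_pool = perm[n_unmappable:]
    memberships = [
        sorted(mappable_pool[j * spec.genes_per_pathway : (j + 1) * spec.genes_per_pathway].tolist())
        for j in range(spec.n_pathways)
    ]
    enriched_genes = set(memberships[0])

    # per-gene hit status: enriched pathway genes at the elevated rate
    u = rng.random(n)
    rate = np.full(n, spec.background_hit_rate)
    rate[sorted(enriched_genes)] = spec.enriched_pathway_rate
    hit_drawn = u < rate

    # value columns: pairs of logFC / P per "time point"
    n_pairs = max(1, spec.n_value_columns // 2)
    logfc_cols = [f"logFC_d{k + 1}" for k in range(n_pairs)]
    p_cols = [f"P.Value_d{k + 1}" for k in range(spec.n_value_columns - n_pairs)]
    columns = logfc_cols + p_cols

    logfc = rng.normal(0.0, 1.0, size=(n, len(logfc_cols)))
    pvals = rng.uniform(0.06, 0.95, size=(n, len(p_cols)))
    if p_cols:  # criterion column encodes hit status exactly
        pvals[:, 0] = np.where(hit_drawn, 0.01, 0.5)
    missing = rng.random((n, len(columns))) < spec.missing_rate

    # effective hit: criterion cell present and below threshold
    crit_idx = len(logfc_cols)  # column index of P.Value_d1 within `columns`
    hit = hit_drawn & ~missing[:, crit_idx] if p_cols else np.zeros(n, bool)

    # ---- measurement table -------------------------------------------------
    data_path = out_dir / "data.tsv"
    with open(data_path, "w", encoding="utf-8") as fh:
        fh.write("GeneID\tSystemCode\t" + "\t".join(columns) + "\n")
        for i in range(n):
            cells = []
            for c in range(len(columns)):
                if missing[i, c]:
                    cells.append("NA")
                elif c < len(logfc_cols):
                    cells.append(f"{logfc[i, c]:.4f}")
                else:
                    cells.append(f"{pvals[i, c - len(logfc_cols)]:.4f}")
            fh.write(f"{entrez[i]}\tL\t" + "\t".join(cells) + "\n")

    # ---- mapping table -----------------------------------------------------
    mapping_path = out_dir / "mapping.tsv"
    with open(mapping_path, "w", encoding="utf-8") as fh:
        fh.write("source_code\tsource_id\ttarget_code\ttarget_id\n")
        fh.write("# synthetic Entrez-like <-> Ensembl-like bijection\n")
        for i in range(n):
            if i in unmappable:
                continue
            fh.write(f"L\t{entrez[i]}\tEn\t{ensembl[i]}\n")

    # ---- pathway collection ------------------------------------------------
    pathway_files = []
    for j, members in enumerate(memberships):
        doc = create_pathway(f"Fixture pathway {j:02d}", spec.organism)
        for gi in members:
            add_data_node(
                doc,
                label=f"Gene{gi}",
                node_type="GeneProduct",
                xref=Xref(identifier=ensembl[gi], system_code="En"),
            )
        path = pathway_dir / f"pw_{j:02d}.gpml"
        write_gpml(doc, path)
        pathway_files.append(path)

    # ---- truth record ------------------------------------------------------
    mappable = [i for i in range(n) if i not in unmappable]
    N = len(mappable)
    R = int(hit[mappable].sum())
    truth = {
        "criterion": CRITERION_TEXT,
        "N": N,
        "R": R,
        "unmappable_rows": n_unmappable,
        "enriched_pathway": "Fixture pathway 00",
        "pathways": {
            f"Fixture pathway {j:02d}": {
                "n": len(members),
                "r": int(hit[members].sum()),
            }
            for j, members in enumerate(memberships)
        },
    }
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n", encoding="utf-8")

    return FixtureResult(
        pathway_dir=pathway_dir,
        pathway_files=pathway_files,
        mapping_path=mapping_path,
        data_path=data_path,
        truth_path=truth_path,
        truth=truth,
    )
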