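"""Shared fixtures: a small generated analysis bundle and random documents."""

from __future__ import annotations

import random

import pytest

from pathviz import (
    FixtureSpec,
    Xref,
    add_data_node,
    add_interaction,
    create_pathway,
    import_data,
    load_mapping_table,
    make_fixture,
    read_gpml,
)
from pathviz.fixtures import CRITERION_TEXT
from pathviz.model import PathwayDoc


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One deterministic fixture bundle, generated once per test session."""
    out = tmp_path_factory.mktemp("bundle")
    fx = make_fixture(FixtureSpec(seed=7, n_genes=300, n_pathways=4, genes_per_pathway=20), out)
    return fx


@pytest.fixture(scope="session")
def bundle_table(bundle):
    return import_data(bundle.data_path, "GeneID", "SystemCode")


@pytest.fixture(scope="session")
def bundle_store(bundle):
    return load_mapping_table(bundle.mapping_path)


@pytest.fixture(scope="session")
def bundle_docs(bundle):
    return [(read_gpml(f), str(f)) for f in bundle.pathway_files]


@pytest.fixture()
def criterion_text():
    return CRITERION_TEXT


@pytest.fixture()
def tiny_mapping(tmp_path):
    """Four pairwise links forming two equivalence sets across three systems."""
    path = tmp_path / "mapping.tsv"
    path.write_text(
        "source_code\tsource_id\ttarget_code\ttarget_id\n"
        "# comment line\n"
        "L\t1234\tEn\tENSG000001\n"
        "En\tENSG000001\tH\tFOS\n"
        "L\t5678\tEn\tENSG000002\n"
        "L\t1234\tEn\tENSG000001\n",  # duplicate row collapses
        encoding="utf-8",
    )
    return load_mapping_table(path)


def make_random_doc(rng: random.Random, max_nodes: int = 8) -> PathwayDoc:
    """Random but valid pathway document (used by round-trip properties)."""
    doc = create_pathway(
        f"pw-{rng.randrange(10**6)}",
        rng.choice(["Homo sapiens", "Mus musculus", ""]),
    )
    n_nodes = rng.randrange(0, max_nodes + 1)
    node_ids = []
    for i in range(n_nodes):
        xref = None
        if rng.random() < 0.6:
            xref = Xref(f"id{rng.randrange(10**5)}", rng.choice(["L", "En", "Ce", "ZZ"]))
        node_ids.append(
            add_data_node(
                doc,
                label=f"gene {i} <&\">",
                node_type=rng.choice(["GeneProduct", "Protein", "Metabolite", "Rna"]),
                xref=xref,
                cx=round(rng.uniform(10, 500), 3) if rng.random() < 0.7 else None,
                cy=round(rng.uniform(10, 400), 3) if rng.random() < 0.7 else None,
                width=round(rng.uniform(20, 120), 3),
                height=round(rng.uniform(10, 40), 3),
            )
        )
    for _ in range(rng.randrange(0, 4)):
        if len(node_ids) >= 1:
            add_interaction(
                doc,
                rng.choice(node_ids),
                rng.choice(node_ids),
                rng.choice(["line", "arrow", "t-bar", "conversion", "catalysis"]),
            )
    if rng.random() < 0.3:
        doc.foreign_blobs.append('<Comment Source="test">opaque &amp; verbatim</Comment>')
    return doc
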