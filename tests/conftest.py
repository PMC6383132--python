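"""Shared fixtures: tiny hand-built structures and a session-scoped
synthetic bundle generated by the package's own generator."""

from __future__ import annotations

import json

import numpy as np
import pytest

from funcdens.structures import ResidueSite, StructureModel, distance_map, load_structure
from funcdens.synthetic import GenerativeConfig, end_to_end_fixture
from funcdens.variants import NormalizedVariant, process_variant_table, read_variant_table


def make_sites(coords, chain="A", aa=None, start=1):
    """Residue sites from a coordinate array, one residue per row."""
    coords = np.asarray(coords, dtype=float)
    aa = aa or ["G"] * len(coords)
    return [
        ResidueSite(chain_id=chain, seq_position=start + i, amino_acid=aa[i],
                    center_of_mass=tuple(float(x) for x in coords[i]))
        for i in range(len(coords))
    ]


def nv(pos, alt="K", delta=100.0, ref="A", gene="SCN5A", parameter="peak_current", **kw):
    """Shorthand normalized-variant record for density/label tests."""
    return NormalizedVariant(
        gene=gene, seq_position=pos, ref_aa=ref, alt_aa=alt,
        parameter=parameter, delta_function=float(delta), **kw,
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The reference synthetic study: 150 variants, one hotspot, noise 20 %WT."""
    out = tmp_path_factory.mktemp("bundle")
    config = GenerativeConfig(seed=1)
    bundle = end_to_end_fixture(config, out)
    structure = load_structure(bundle.structure_path)
    distances = distance_map(structure)
    table = read_variant_table(bundle.variants_path)
    aggregated = process_variant_table(table.records)
    truth = json.loads(bundle.truth_path.read_text())
    return {
        "bundle": bundle,
        "config": config,
        "structure": structure,
        "distances": distances,
        "table": table,
        "aggregated": aggregated,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
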