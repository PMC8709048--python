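"""Shared fixtures: the TOY4 file-based gene model and the synthetic
RAS-like preset bundles (session-scoped; catalogs are reused across tests)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

import pytest

import junctionscout as js
from junctionscout.presets import PRESET_SAMPLES, preset_abundances, preset_gene

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy4_paths():
    return {"model": DATA / "toy4.json", "fasta": DATA / "toy4.fa"}


@pytest.fixture(scope="session")
def toy4(toy4_paths):
    return js.load_gene_model(toy4_paths["model"], toy4_paths["fasta"])


@pytest.fixture(scope="session")
def toy4_minus():
    return js.load_gene_model(DATA / "toy4_minus.json", DATA / "toy4_minus.fa")


@pytest.fixture(scope="session")
def toy4_raw(toy4_paths):
    """The raw fixture sequence, read independently of the model class."""
    lines = toy4_paths["fasta"].read_text().splitlines()
    return "".join(l for l in lines if not l.startswith(">"))


@dataclass
class PresetBundle:
    model: js.GeneModel
    annotated: list
    novels: list
    primers: js.PrimerPair
    catalog: js.JunctionCatalog

    @property
    def planted(self):
        return self.annotated + self.novels


def _bundle(gene: str) -> PresetBundle:
    model, annotated, novels, primers = preset_gene(gene)
    catalog = js.build_catalog(model, primers=primers)
    return PresetBundle(model, annotated, novels, primers, catalog)


@pytest.fixture(scope="session")
def kras():
    return _bundle("KRAS")


@pytest.fixture(scope="session")
def nras():
    return _bundle("NRAS")


@pytest.fixture(scope="session")
def hras():
    return _bundle("HRAS")


@pytest.fixture(scope="session")
def ras_bundles(kras, nras, hras):
    return {"KRAS": kras, "NRAS": nras, "HRAS": hras}


def simulate_bundle(bundle: PresetBundle, seed: int, coverage=None, error_free=False):
    """Simulate reads for a preset bundle; returns (reads, truth, abundances)."""
    from junctionscout.simulate import SimulationConfig, simulate_reads

    kwargs = {}
    if error_free:
        kwargs = dict(sub_rate=0.0, ins_rate=0.0, del_rate=0.0, truncation_prob=0.0)
    cfg = SimulationConfig(seed=seed, **kwargs)
    abund = preset_abundances(bundle.annotated, bundle.novels, coverage=coverage)
    reads, truth = simulate_reads(bundle.model, cfg, bundle.planted, abund)
    return reads, truth


def scan_all(bundle: PresetBundle, reads: Dict[str, list], params=None):
    from junctionscout.scanner import ScanParams, process_read

    params = params or ScanParams()
    evidence = []
    for sample, lst in reads.items():
        for rid, seq in lst:
            evidence.append(
                process_read(rid, seq, bundle.catalog, bundle.model, params, sample=sample)
            )
    return evidence
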