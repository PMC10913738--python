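"""Shared fixtures: tiny hand-built tables and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wamecfix.io import (
    RANKS,
    UNCLASSIFIED,
    PathwaySet,
    SampleTable,
    UnigeneCatalog,
    load_default_pathways,
)


def make_catalog(rows: list[dict]) -> UnigeneCatalog:
    """Build a catalog from shorthand dicts:
    {id, length, supergroup?, order?, kos?, pfams?}."""
    records = []
    for r in rows:
        rec = {
            "unigene_id": r["id"],
            "length_bp": int(r.get("length", 1000)),
            "domain": r.get("domain", "Eukaryota"),
            "supergroup": r.get("supergroup", UNCLASSIFIED),
            "phylum": r.get("supergroup", UNCLASSIFIED),
            "class": UNCLASSIFIED,
            "order": r.get("order", UNCLASSIFIED),
            "genus": UNCLASSIFIED,
            "species": UNCLASSIFIED,
            "ko_ids": frozenset(r.get("kos", ())),
            "pfam_ids": frozenset(r.get("pfams", ())),
        }
        records.append(rec)
    frame = pd.DataFrame(records).set_index("unigene_id")
    return UnigeneCatalog(frame)


def make_samples(n_libs: int, fractions=("small",), yields=(1.0, 1.5)) -> SampleTable:
    """n_libs libraries split over stations, one layer, given fractions,
    two replicates per condition."""
    rows = []
    i = 0
    rep = 1
    station = 0
    while i < n_libs:
        for fr, y in zip(fractions, yields):
            if i >= n_libs:
                break
            rows.append(
                {
                    "library_id": f"L{i:02d}",
                    "station": f"st{station}",
                    "layer": "SUR",
                    "size_fraction": fr,
                    "replicate": rep,
                    "rna_yield_per_L": y,
                    "temperature": 25.0 + station,
                }
            )
            i += 1
        if rep == 2:
            rep = 1
            station += 1
        else:
            rep += 1
    return SampleTable(pd.DataFrame(rows).set_index("library_id"))


@pytest.fixture(scope="session")
def pathways() -> PathwaySet:
    return load_default_pathways()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
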