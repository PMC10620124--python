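"""Shared fixtures: tiny in-memory concentration tables built from dicts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lipidiff import nomenclature
from lipidiff.ingest import ConcentrationTable


def make_table(
    values: dict[str, list[float | None]],
    groups: list[tuple[str, str]],
    unit: str = "pmol",
) -> ConcentrationTable:
    """Build a ConcentrationTable from {lipid_name: per-sample values}.

    ``groups`` gives each sample's (cell_line, treatment); replicate
    numbers are assigned within each group in order.  ``None`` entries
    become missing cells.
    """
    lipids = [nomenclature.parse_species(name) for name in values]
    counter: dict[tuple[str, str], int] = {}
    rows = []
    for cell, treat in groups:
        counter[(cell, treat)] = counter.get((cell, treat), 0) + 1
        rows.append(
            {
                "sample_id": f"{cell}_{treat}_r{counter[(cell, treat)]}",
                "cell_line": cell,
                "treatment": treat,
                "replicate": counter[(cell, treat)],
            }
        )
    samples = pd.DataFrame(rows).set_index("sample_id")
    grid = pd.DataFrame(
        [[np.nan if v is None else float(v) for v in row] for row in values.values()],
        index=pd.Index(
            [nomenclature.canonical_name(s) for s in lipids], name="lipid"
        ),
        columns=samples.index,
    )
    return ConcentrationTable(values=grid, lipids=lipids, samples=samples, unit=unit)


def random_species_name(rng: np.random.Generator) -> str:
    """A grammar-random shorthand name over the full class ontology."""
    lipid_class = str(rng.choice(list(nomenclature.CLASS_TABLE)))
    arity = nomenclature.arity_of(lipid_class)
    chains = []
    for _ in range(arity):
        c = int(rng.integers(1, 40))
        d = int(rng.integers(0, 7))
        h = int(rng.integers(0, 4))
        chains.append(f"{c}:{d}" + (f";{h}" if h else ""))
    return f"{lipid_class} {'/'.join(chains)}"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
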