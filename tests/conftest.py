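"""Shared fixtures: tiny deterministic layouts and arrays."""

import numpy as np
import pandas as pd
import pytest

from monomark import (
    ArrayLayout,
    ArrayTruthModel,
    PeptideSpec,
    normalize_intensities,
    parse_mod_tag,
    simulate_array,
)


def make_layout(spot_mods, n_subarrays=2, controls=("blank",)):
    """One-column layout from a list of mod-name lists (None = control)."""
    entries = list(spot_mods) + [None] * len(controls)
    spots = {}
    control_iter = iter(controls)
    used_controls = []
    for r, mods in enumerate(entries, start=1):
        if mods is None:
            label = next(control_iter)
            used_controls.append(label)
            for s in range(1, n_subarrays + 1):
                spots[(s, r, 1)] = label
            continue
        tags = frozenset(parse_mod_tag(m) for m in mods)
        histone = next(iter(tags)).histone if tags else "H3"
        positions = [t.position for t in tags]
        start = max(1, min(positions) if positions else 1)
        if positions and max(positions) - start > 18:
            start = max(positions) - 18
        spec = PeptideSpec(
            spot_id=f"r{r}c1", histone=histone, span=(start, start + 18), mods=tags
        )
        for s in range(1, n_subarrays + 1):
            spots[(s, r, 1)] = spec
    return ArrayLayout(shape=(len(entries), 1), n_subarrays=n_subarrays, spots=spots)


def result_from_values(layout, values_by_subarray):
    """ArrayResult from explicit per-subarray corrected values (peptides only)."""
    rows = []
    ids = layout.spot_ids()
    for subarray, values in values_by_subarray.items():
        assert len(values) == len(ids)
        for sid, v in zip(ids, values):
            rows.append((sid, subarray, float(v)))
    for pos, label in layout.control_spot_ids().items():
        rows.append((label, pos[0], 0.0))
    table = pd.DataFrame(rows, columns=["spot_id", "subarray", "corrected"])
    return normalize_intensities(table, layout, method="max")


@pytest.fixture
def toy_layout():
    """Eight peptides over five marks plus a blank control, duplicated."""
    return make_layout(
        [
            ["H4K20me1"],
            ["H4K20me1"],
            ["H3K4me1"],
            ["H3K9me3"],
            ["H3K9me3"],
            ["H3K4me1", "H3K9me3"],
            ["H3K4me1", "H3K9me2"],
            [],
        ]
    )


@pytest.fixture
def noiseless_array(toy_layout):
    truth = ArrayTruthModel(
        affinities={"H4K20me1": 2.0, "H3K4me1": 1.5},
        noise_cv=0.0,
        background=0.0,
        seed=0,
    )
    result, truth_table = simulate_array(truth, toy_layout)
    return result, truth_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
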