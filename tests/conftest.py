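"""Shared fixtures: small phantoms and cohorts built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import marbleye as me

BOARD = (120, 120, 120)
LEAN = (150, 62, 58)
FAT = (235, 210, 185)


def hard_disk_image(size=200, center=(100, 100), radius=60, bg=BOARD, fg=LEAN):
    """A hard-edged (non-anti-aliased) disk on a uniform board."""
    yy, xx = np.mgrid[0:size, 0:size]
    disk = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    pixels = np.empty((size, size, 3), np.uint8)
    pixels[:] = bg
    pixels[disk] = fg
    return me.RibEyeImage(pixels=pixels, px_per_mm=4.0), disk


@pytest.fixture
def small_spec():
    """A quick-to-render phantom spec with a handful of flecks."""
    return me.PhantomSpec(n_small=8, n_large=1, seed=42)


@pytest.fixture
def small_phantom(small_spec):
    return me.render_phantom(small_spec)


@pytest.fixture(scope="session")
def tiny_design():
    """A 12-sample cohort design that keeps rendering cheap."""
    return me.CohortDesign(
        animals_per_breed=2, replicates_per_animal=2, images_per_sample=4, seed=5
    )


@pytest.fixture(scope="session")
def tiny_truth_table(tiny_design):
    return me.generate_cohort(tiny_design).truth_feature_table()


def rescored(table: pd.DataFrame, score_model: me.ScoreModel, seed: int,
             permute: bool = False) -> pd.DataFrame:
    """Replace the table's scores with fresh draws from ``score_model``."""
    feats = table.drop_duplicates("sample_id")
    rng = np.random.default_rng(seed)
    scores = me.assign_scores(feats, score_model, rng)
    if permute:
        scores = rng.permutation(scores)
    mapping = dict(zip(feats["sample_id"], scores))
    out = table.copy()
    out["score"] = out["sample_id"].map(mapping)
    return out
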