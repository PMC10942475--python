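import numpy as np
import pandas as pd
import pytest

from motifdiff.core_io import FragmentSet
from motifdiff.synthfix import FixtureSpec, generate_fixture


def make_fragments(rows, sample_id="s", gc=None):
    """Build a FragmentSet from (chrom, start, end[, weight]) tuples."""
    recs = []
    for r in rows:
        chrom, start, end = r[:3]
        weight = r[3] if len(r) > 3 else 1
        recs.append((chrom, start, end, weight))
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "weight"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["weight"] = df["weight"].astype(np.int64)
    if gc is not None:
        df["gc"] = np.asarray(gc, dtype=float)
    return FragmentSet(sample_id, df)


@pytest.fixture(scope="session")
def small_bundle():
    """Small perturbed fixture shared by read-only tests."""
    return generate_fixture(
        FixtureSpec(n_peaks=400, n_motifs=30, n_network=5, n_archetype_twins=3, seed=7)
    )


@pytest.fixture(scope="session")
def null_bundle():
    """Unperturbed (strength 0) fixture."""
    return generate_fixture(
        FixtureSpec(n_peaks=400, n_motifs=30, n_network=5, n_archetype_twins=3,
                    strength=0.0, seed=11)
    )
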