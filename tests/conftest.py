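import numpy as np
import pytest

from cannamark import association
from cannamark.simulate import PanelConfig, simulate_panel


@pytest.fixture(scope="session")
def default_panel():
    """The full default study panel: 47+50 plants, 20+50 seeds, seeded."""
    return simulate_panel(PanelConfig(seed=1))


@pytest.fixture(scope="session")
def default_scan(default_panel):
    return association.scan_loci(default_panel.matrix, q=0.05)


@pytest.fixture(scope="session")
def clean_small_panel():
    """A small noise-free panel (no background mutation, no heterozygosity)."""
    cfg = PanelConfig(
        seed=5,
        n_drug_plants=6,
        n_fiber_plants=6,
        n_drug_seeds=2,
        n_fiber_seeds=2,
        het_rate=0.0,
        background_mutation_rate=0.0,
    )
    return simulate_panel(cfg)


def auc_pair_enumeration(scores, labels):
    """Independent AUC oracle: enumerate every drug/fiber pair, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    drug = scores[labels == "drug"]
    fiber = scores[labels == "fiber"]
    total = 0.0
    for d in drug:
        for f in fiber:
            total += 1.0 if d > f else (0.5 if d == f else 0.0)
    return total / (len(drug) * len(fiber))


def brute_force_alignment_score(
    a, b, match=2.0, mismatch=-3.0, gap_open=-5.0, gap_extend=-2.0
):
    """Exhaustive global-alignment oracle (affine gaps: open + L*extend).

    Enumerates every monotone alignment of two short sequences; only
    feasible for lengths of about 8 or less.
    """
    best = -np.inf

    def rec(i, j, prev, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            pen = gap_extend + (gap_open if prev != "D" else 0.0)
            rec(i + 1, j, "D", score + pen)
        if j < len(b):
            pen = gap_extend + (gap_open if prev != "I" else 0.0)
            rec(i, j + 1, "I", score + pen)

    rec(0, 0, None, 0.0)
    return best
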