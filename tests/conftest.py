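import numpy as np
import pytest

import grainscan as gs


@pytest.fixture(scope="session")
def default_config():
    return gs.PipelineConfig()


@pytest.fixture(scope="session")
def small_field():
    """A 12-grain wheat scene with ground truth (session-cached)."""
    spec = gs.wheat_spec(n_grains=12, seed=1)
    image, truth = gs.render_grain_field(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def clean_card():
    """A noiseless synthetic colour-checker card with its true transform."""
    return gs.render_colour_card(noise_sd=0.0, seed=7)


def match_to_truth(records, truth):
    """Map each measured grain to the truth grain under its centroid."""
    tl = truth.labels.labels
    pairs = []
    for rec in records:
        r, c = (int(round(v)) for v in rec.centroid_px)
        tid = int(tl[r, c])
        if tid > 0:
            pairs.append((rec, truth.table.iloc[tid - 1]))
    return pairs


def count_matches(pred_labels, truth_labels):
    """Greedy majority-overlap matching; returns (n_matched, n_pred, n_true)."""
    pl = pred_labels.labels
    tl = truth_labels.labels
    n_true = truth_labels.n_objects
    n_pred = pred_labels.n_objects
    matched = 0
    used = set()
    for tid in range(1, n_true + 1):
        m = tl == tid
        overlap = np.bincount(pl[m], minlength=n_pred + 1)
        overlap[0] = 0
        if overlap.sum() == 0:
            continue
        best = int(overlap.argmax())
        if best not in used and overlap[best] > 0.5 * m.sum():
            used.add(best)
            matched += 1
    return matched, n_pred, n_true
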