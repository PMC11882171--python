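import numpy as np
import pytest

from t1rr import (compute_rr_map, compute_t1_map, make_rr_validation_phantom,
                  render_pair)

PROTOCOL = dict(tr=5.0, pre_angles=(5.0, 15.0), post_angles=(5.0, 20.0))


def run_phantom_pipeline(pre_spec, post_spec, smooth=True, seed=None, **kw):
    """Render pre/post dual-angle acquisitions and compute T1 + RR maps."""
    pl, ph = render_pair(pre_spec, PROTOCOL["pre_angles"], PROTOCOL["tr"],
                         seed=seed)
    ql, qh = render_pair(post_spec, PROTOCOL["post_angles"], PROTOCOL["tr"],
                         seed=None if seed is None else seed + 1)
    t1_pre = compute_t1_map(pl, ph, smooth=smooth, phase_label="pre", **kw)
    t1_post = compute_t1_map(ql, qh, smooth=smooth, phase_label="post", **kw)
    return t1_pre, t1_post, compute_rr_map(t1_pre, t1_post)


@pytest.fixture(scope="session")
def noiseless_validation_pipeline():
    """Noiseless 8-slot validation phantom run end to end (shared, read-only)."""
    pre_spec, post_spec = make_rr_validation_phantom()
    t1_pre, t1_post, rr = run_phantom_pipeline(pre_spec, post_spec)
    return pre_spec, post_spec, t1_pre, t1_post, rr
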