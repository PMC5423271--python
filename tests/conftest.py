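"""Shared fixtures: synthetic stacks and pre-fitted phantom segmentations."""

import numpy as np
import pytest

import multiseg as ms


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_volume(data, voxel=1.0):
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel
    return ms.Volume(np.asarray(data, dtype=float), aff)


@pytest.fixture()
def two_cluster_stack(rng):
    """10x10x10 single-channel stack drawn from two unit-variance Gaussians."""
    data = np.concatenate([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
    rng.shuffle(data)
    vol = make_volume(data.reshape(10, 10, 10))
    return ms.stack_channels([vol], ["t1w"])


@pytest.fixture(scope="session")
def dura_phantom():
    """Default 40^3 confound phantom with priors and multi-echo series."""
    spec = ms.PhantomSpec(shape=(40, 40, 40), seed=3)
    stack, series, truth = ms.generate(spec)
    priors = ms.make_priors(truth)
    return {"spec": spec, "stack": stack, "series": series,
            "truth": truth, "priors": priors}


@pytest.fixture(scope="session")
def combo_fits(dura_phantom):
    """Fitted results for the four channel combinations on the phantom.

    The R2* channel is estimated from the rendered multi-echo series, as in
    the full pipeline; session-scoped because four EM fits are the most
    expensive shared ingredient of the comparison tests.
    """
    stack = dura_phantom["stack"]
    series = dura_phantom["series"]
    priors = dura_phantom["priors"]
    r2map = ms.fit_r2star(series)
    rate = np.where(r2map.valid.data.astype(bool), r2map.rate.data, 0.0)
    full = ms.ChannelStack(
        stack.channels + [stack.grid.like(rate)],
        stack.channel_names + ["r2star"],
        mask=stack.mask,
    )
    fits = {}
    for chans in (["t1w"], ["t1w", "flair"], ["t1w", "r2star"],
                  ["t1w", "flair", "r2star"]):
        name = "+".join(chans)
        fits[name] = ms.MultichannelMixture(
            full.subset(chans), priors=priors
        ).fit(seed=1)
    return fits
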