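"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's vectorized code paths: naive
triple loops over pixels and covering patches, and a direct Mann–Whitney
pair count for AUC.
"""

from __future__ import annotations

import numpy as np
import pytest

from dynqc import MaskSeries, PhantomSpec, SimSegmenterSpec, generate_phantom


def naive_aggregate(stack, grid, mode):
    """Brute-force per-pixel aggregation over covering patches."""
    P, K, _, T = stack.shape
    out = np.zeros((grid.M, grid.N, T))
    for m in range(grid.M):
        for n in range(grid.N):
            cover = [
                i
                for i, (r, c) in enumerate(grid.origins)
                if r <= m < r + K and c <= n < c + K
            ]
            for t in range(T):
                vals = np.array([stack[i, m - grid.origins[i][0], n - grid.origins[i][1], t] for i in cover])
                out[m, n, t] = vals.mean() if mode == "mean" else vals.std()
    return out


def pair_count_auc(scores, labels):
    """Mann–Whitney AUC: concordant pairs / (n1 * n0), ties worth 0.5."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def lookup_segmenter(stack, grid):
    """Segmenter that replays a precomputed per-patch probability stack."""
    origin_to_idx = {o: i for i, o in enumerate(grid.origins)}

    def seg(patch, origin):
        return stack[origin_to_idx[origin]]

    return seg


def constant_field_segmenter(field):
    """Position-agnostic segmenter: a fixed per-pixel function of global coords."""

    def seg(patch, origin):
        r, c = origin
        kr, kc, _ = patch.shape
        return field[r : r + kr, c : c + kc, :]

    return seg


def make_mask(arr, role="prediction"):
    return MaskSeries(np.asarray(arr, dtype=np.uint8), role=role)


SMALL_SPEC = PhantomSpec(
    M=48,
    N=48,
    T=10,
    center=(24.0, 24.0),
    r_inner=6.0,
    r_outer=11.0,
    breath_amplitude=1.5,
    seed=5,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A 48x48x10 phantom, cheap enough for unit tests."""
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_segmenter(small_bundle):
    return lambda spec=None: __import__("dynqc").make_sim_segmenter(
        small_bundle, spec if spec is not None else SimSegmenterSpec(seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
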