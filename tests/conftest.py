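"""Shared fixtures and random-instance generators for the test suite."""

import numpy as np
import pytest

from octal import random_binary_tree


def make_labels(n, prefix="s"):
    return [f"{prefix}{i:02d}" for i in range(n)]


def random_instance(rng, n_min=5, n_max=8, max_missing=3):
    """A random (reference, gene) pair: the reference is a uniform random
    binary tree on S, the gene an independent random binary tree on a random
    subset R with |S ∖ R| missing taxa and |R| >= 3."""
    n = int(rng.integers(n_min, n_max + 1))
    labels = make_labels(n)
    reference = random_binary_tree(labels, rng)
    k_max = min(max_missing, n - 3)
    k = int(rng.integers(1, k_max + 1))
    keep = sorted(str(x) for x in rng.choice(labels, size=n - k, replace=False))
    gene = random_binary_tree(keep, rng)
    return reference, gene


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
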