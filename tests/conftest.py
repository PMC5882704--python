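"""Shared fixtures: small hand-built trees and random generators."""

from __future__ import annotations

import numpy as np
import pytest

from fossilrange.data import AgeTable, GeographyTable
from fossilrange.model import ModelParams, ModelSpec, StateSpace, Stratum
from fossilrange.trees import Node, TimeTree


def make_timetree(newick_ages) -> TimeTree:
    """Build a TimeTree from a nested (label, age) structure.

    Example: ``(((("T1", 10), ("T2", 20)), 50),)`` is not used; instead pass
    a nested tuple ``(age, child, child)`` for internals and ``(label, age)``
    for leaves.
    """
    def build(spec):
        if isinstance(spec[0], str):
            return Node(label=spec[0], age=float(spec[1]))
        node = Node(age=float(spec[0]))
        for child in spec[1:]:
            node.add_child(build(child))
        return node

    return TimeTree(build(newick_ages))


@pytest.fixture
def two_tip_tree() -> TimeTree:
    return make_timetree((50.0, ("T1", 10.0), ("T2", 20.0)))


@pytest.fixture
def four_tip_tree() -> TimeTree:
    return make_timetree(
        (100.0,
         (80.0, ("T1", 30.0), ("T2", 10.0)),
         (60.0, ("T3", 20.0), ("T4", 5.0)))
    )


@pytest.fixture
def one_stratum():
    return [Stratum(120.0, 0.0)]


def random_timetree(rng: np.random.Generator, n_tips: int,
                    root_age: float = 100.0) -> TimeTree:
    """Random topology (uniform ordered splits) with random valid ages."""
    counter = [0]

    def build(n, age):
        if n == 1:
            counter[0] += 1
            leaf_age = age * rng.uniform(0.0, 0.9)
            return Node(label=f"T{counter[0]}", age=leaf_age)
        k = int(rng.integers(1, n))
        node = Node(age=age)
        for size in (k, n - k):
            child_age = age * rng.uniform(0.3, 0.95)
            child = build(size, child_age)
            node.add_child(child)
        return node

    root = Node(age=root_age)
    k = int(rng.integers(1, n_tips)) if n_tips > 1 else 1
    for size in (k, n_tips - k):
        root.add_child(build(size, root_age * rng.uniform(0.3, 0.95)))
    return TimeTree(root)


def random_geography(rng: np.random.Generator, labels, nareas: int,
                     m: int | None = None) -> GeographyTable:
    m = m or nareas
    areas = [chr(ord("A") + i) for i in range(nareas)]
    ranges = {}
    for lab in labels:
        size = int(rng.integers(1, m + 1))
        chosen = rng.choice(nareas, size=size, replace=False)
        ranges[lab] = int(sum(1 << int(i) for i in chosen))
    return GeographyTable(areas, ranges)


def random_agetable(rng: np.random.Generator, labels,
                    max_age: float = 100.0) -> AgeTable:
    fad, lad = {}, {}
    for lab in labels:
        f = float(rng.uniform(0, max_age))
        fad[lab] = f
        lad[lab] = float(rng.uniform(0, f))
    return AgeTable(fad, lad)
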