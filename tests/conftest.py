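"""Shared fixtures: exhaustive tree catalogues and brute-force helpers."""

from __future__ import annotations

import itertools

import pytest

from lincr import parse_newick


def _partitions(seq: list):
    """All set partitions of ``seq`` (each exactly once)."""
    if len(seq) == 1:
        yield [seq]
        return
    head, rest = seq[0], seq[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
        yield [[head]] + part


def _subtree_newicks(labels: tuple[str, ...]) -> list[str]:
    """Newick fragments of all rooted phylogenetic trees on ``labels``."""
    if len(labels) == 1:
        return [labels[0]]
    out: list[str] = []
    for part in _partitions(list(labels)):
        if len(part) < 2:
            continue
        block_choices = [_subtree_newicks(tuple(block)) for block in part]
        for combo in itertools.product(*block_choices):
            out.append("(" + ",".join(combo) + ")")
    return out


def all_phylo_newicks(labels: tuple[str, ...]) -> list[str]:
    """Newick strings of every rooted phylogenetic tree on ``labels``."""
    return [s + ";" for s in _subtree_newicks(labels)]


LABELS = "abcdefgh"


@pytest.fixture(scope="session")
def tree_catalogue():
    """All phylogenetic trees (as Newick strings) on n = 2..5 leaves."""
    return {n: all_phylo_newicks(tuple(LABELS[:n])) for n in range(2, 6)}


@pytest.fixture()
def parse():
    return parse_newick


def brute_force_is_hierarchy(cluster_set, ground_set) -> bool:
    """Independent pairwise-intersection hierarchy test (test oracle)."""
    H = set(cluster_set)
    if ground_set not in H:
        return False
    if any(frozenset((x,)) not in H for x in ground_set):
        return False
    if any(not c for c in H):
        return False
    for a, b in itertools.combinations(H, 2):
        inter = a & b
        if inter and inter != a and inter != b:
            return False
    return True
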