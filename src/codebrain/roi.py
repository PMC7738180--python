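"""Subject-specific functional ROIs: top-k vertex selection in fixed search spaces."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .glm import VertexMap

__all__ = ["SearchSpace", "FunctionalROI", "select_top_k", "default_search_spaces"]

SEARCH_SPACE_NAMES = ("IPS", "pMTG", "PFC", "Occ")


@dataclass
class SearchSpace:
    """A fixed group-level search space: a named set of vertex indices in one hemisphere."""

    name: str
    vertices: np.ndarray
    hemisphere: str = "L"

    def __post_init__(self):
        self.vertices = np.asarray(sorted(set(int(v) for v in np.asarray(self.vertices).ravel())))
        if self.vertices.size == 0:
            raise ValueError("search space must be non-empty")

    def __len__(self) -> int:
        return self.vertices.size


@dataclass
class FunctionalROI:
    subject: str
    space: str
    vertices: np.ndarray
    k: int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices)


def select_top_k(contrast: VertexMap, space: SearchSpace, k: int = 500,
                 subject: str = "") -> FunctionalROI:
    """Select the k search-space vertices with the largest contrast statistic.

    "Active" means largest statistic value, with no significance gate; ties
    break deterministically by ascending vertex index.  Raises if the search
    space holds fewer than k vertices (no silent truncation).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(space) < k:
        raise ValueError(
            f"search space {space.name!r} has {len(space)} vertices, fewer than k={k}"
        )
    idx = space.vertices
    vals = contrast.values[idx]
    order = np.lexsort((idx, -vals))  # descending value, ascending index on ties
    selected = np.sort(idx[order[:k]])
    return FunctionalROI(subject=subject, space=space.name, vertices=selected, k=k)


def default_search_spaces(n_vertices_per_hemi: int) -> list[SearchSpace]:
    """Partition the left hemisphere into the four named search spaces.

    The synthetic cortical sheet has no geometry, so the spaces are equal
    contiguous blocks of left-hemisphere vertex indices (IPS, pMTG, PFC, Occ).
    """
    edges = np.linspace(0, n_vertices_per_hemi, len(SEARCH_SPACE_NAMES) + 1).astype(int)
    return [
        SearchSpace(name=name, vertices=np.arange(edges[i], edges[i + 1]), hemisphere="L")
        for i, name in enumerate(SEARCH_SPACE_NAMES)
    ]


def save_spaces(spaces: list[SearchSpace], path) -> None:
    payload = [
        {"name": s.name, "hemisphere": s.hemisphere, "vertices": s.vertices.tolist()}
        for s in spaces
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_spaces(path) -> list[SearchSpace]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        SearchSpace(name=d["name"], vertices=np.asarray(d["vertices"]), hemisphere=d["hemisphere"])
        for d in payload
    ]
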