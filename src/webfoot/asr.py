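"""Ancestral state reconstruction of a multistate character, statsmodels-style.

The modelling surface is :class:`MkAncestralModel` (tree + tip states), whose
``fit`` estimates the single Mk rate by maximum likelihood (or accepts a fixed
rate) and returns :class:`MkAncestralResults`: marginal state probabilities at
every internal node, the fitted rate and log-likelihood, a ``summary()``
table, most-probable (MAP) states with tie flags, and a count of independent
origins of a set of target states (e.g. the four webbed-foot types) along the
tree.

Free functions ``reconstruct``, ``most_probable_states`` and
``count_independent_origins`` expose the same steps for scripted use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .characters import CharacterStateMap
from .errors import ValidationError
from .mk import (
    DEFAULT_RATE_BOUNDS,
    DEFAULT_RATE_TOL,
    AncestralReconstruction,
    MkModel,
    fit_rate,
    marginal_asr,
    tree_log_likelihood,
)
from .tree import PhyloTree, read_newick

__all__ = [
    "MkAncestralModel",
    "MkAncestralResults",
    "reconstruct",
    "most_probable_states",
    "count_independent_origins",
]


def reconstruct(
    tree: PhyloTree,
    states: CharacterStateMap,
    k: int | None = None,
    rate: float | None = None,
    bounds=DEFAULT_RATE_BOUNDS,
    tol: float = DEFAULT_RATE_TOL,
) -> AncestralReconstruction:
    """Fit the Mk rate on the single character (unless ``rate`` is given) and
    return the marginal reconstruction at that rate."""
    if k is None:
        k = states.k
    if rate is None:
        model, _ = fit_rate(tree, [states], k, bounds=bounds, tol=tol)
    else:
        model = MkModel(k, rate)
    return marginal_asr(tree, states, model)


def most_probable_states(recon: AncestralReconstruction):
    """MAP state per node (internal nodes and tips).

    Returns ``(states, ties)``: a dict node index -> argmax state (ties broken
    towards the lowest state index) and the set of node indices where the
    maximum was tied (within 1e-12).
    """
    states, ties = {}, set()
    for v, p in recon.all_probabilities().items():
        s = int(np.argmax(p))
        states[v] = s
        if np.sum(np.abs(p - p[s]) <= 1e-12) > 1:
            ties.add(v)
    return states, ties


def count_independent_origins(tree: PhyloTree, node_states: dict, target_states) -> int:
    """Number of edges on which a target state was gained.

    An origin is an edge whose child state is in ``target_states`` while the
    parent state is not (tips count as children). ``node_states`` must cover
    every node of the tree.
    """
    target = {int(s) for s in target_states}
    missing = [v for v in range(tree.n_nodes) if v not in node_states]
    if missing:
        raise ValidationError(f"node_states missing nodes {missing}")
    count = 0
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        if node_states[v] in target and node_states[p] not in target:
            count += 1
    return count


class MkAncestralModel:
    """Mk-model ancestral reconstruction of one discrete character.

    Parameters
    ----------
    tree : PhyloTree
        Rooted tree; for the standard "unscaled" analysis all branch lengths
        are 1 (Newick input without lengths already defaults to 1).
    states : CharacterStateMap
        Tip label -> state index (``None`` for missing).
    k : int, optional
        Number of states; defaults to ``states.k``.
    """

    def __init__(self, tree: PhyloTree, states: CharacterStateMap, k: int | None = None):
        self.tree = tree
        self.states = states
        self.k = int(k) if k is not None else states.k
        if self.k < states.k and max(states.observed_states(), default=0) >= self.k:
            raise ValidationError("observed states exceed requested k")

    @classmethod
    def from_files(cls, tree_path, states_path, k: int | None = None, unscaled: bool = False):
        tree = read_newick(Path(tree_path).read_text(), force_unit_lengths=unscaled)
        states = CharacterStateMap.from_tsv(states_path, k=k)
        return cls(tree, states, k=k)

    def loglike(self, rate: float) -> float:
        return tree_log_likelihood(self.tree, self.states, MkModel(self.k, rate))

    def fit(
        self,
        rate: float | None = None,
        bounds=DEFAULT_RATE_BOUNDS,
        tol: float = DEFAULT_RATE_TOL,
    ) -> "MkAncestralResults":
        recon = reconstruct(self.tree, self.states, k=self.k, rate=rate, bounds=bounds, tol=tol)
        return MkAncestralResults(self, recon, rate_fixed=rate is not None)


@dataclass
class MkAncestralResults:
    model: MkAncestralModel
    recon: AncestralReconstruction
    rate_fixed: bool = False

    @property
    def rate(self) -> float:
        return self.recon.rate

    @property
    def log_likelihood(self) -> float:
        return self.recon.log_likelihood

    @property
    def k(self) -> int:
        return self.recon.k

    def node_probabilities(self, include_tips: bool = False) -> pd.DataFrame:
        """Tidy per-node table: node, label, p_state0..p_state{k-1}, map_state, tie."""
        tree = self.model.tree
        states, ties = most_probable_states(self.recon)
        probs = self.recon.all_probabilities() if include_tips else self.recon.node_probabilities
        rows = []
        for v in sorted(probs):
            p = probs[v]
            row = {"node_id": v, "label": tree.node_name(v), "is_tip": tree.is_tip(v)}
            for s in range(self.k):
                row[f"p_state{s}"] = p[s]
            row["map_state"] = states[v]
            row["tie_flag"] = v in ties
            rows.append(row)
        return pd.DataFrame(rows)

    def most_probable_states(self, tips_from_data: bool = True):
        """MAP state for every node; observed tips keep their coded state."""
        states, ties = most_probable_states(self.recon)
        if tips_from_data:
            tree = self.model.tree
            for tip in tree.tips:
                s = self.model.states[tree.labels[tip]]
                if s is not None:
                    states[int(tip)] = int(s)
                    ties.discard(int(tip))
        return states, ties

    def count_independent_origins(self, target_states) -> int:
        states, _ = self.most_probable_states()
        return count_independent_origins(self.model.tree, states, target_states)

    def annotated_newick(self) -> str:
        """Newick with ``[&p={...}]`` comments holding node probabilities."""
        ann = {}
        for v, p in self.recon.node_probabilities.items():
            body = ",".join(f"{s}:{p[s]:.6f}" for s in range(self.k))
            ann[v] = "&p={" + body + "}"
        return self.model.tree.newick(annotations=ann)

    def summary(self) -> str:
        tree = self.model.tree
        lines = [
            "Mk ancestral state reconstruction",
            "=" * 45,
            f"states (k):           {self.k}",
            f"tips:                 {tree.n_tips}",
            f"internal nodes:       {len(self.recon.node_probabilities)}",
            f"rate r ({'fixed' if self.rate_fixed else 'ML'}):        {self.rate:.6g}",
            f"log-likelihood:       {self.log_likelihood:.6f}",
            "",
            "Root state probabilities:",
        ]
        root_p = self.recon.node_probabilities[int(tree.root)]
        for s in range(self.k):
            lines.append(f"  state {s}: {root_p[s]:.4f}")
        return "\n".join(lines)

    def save(self, outdir, seed: int | None = None) -> dict:
        """Write node-probability TSV, annotated Newick and a JSON run report;
        returns the report dict."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = self.node_probabilities(include_tips=True)
        df.to_csv(outdir / "node_probabilities.tsv", sep="\t", index=False, float_format="%.10g")
        (outdir / "annotated_tree.nwk").write_text(self.annotated_newick() + "\n")
        report = {
            "tool": "webfoot",
            "version": _version,
            "analysis": "asr",
            "k": self.k,
            "rate": self.rate,
            "rate_fixed": self.rate_fixed,
            "log_likelihood": self.log_likelihood,
            "n_tips": int(self.model.tree.n_tips),
            "seed": seed,
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        return report
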