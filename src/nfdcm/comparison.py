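"""Bayesian model comparison between field and mass variants.

Fitted models are compared through their free energies (log-evidence
bounds): a difference of three nats or more in favour of one model is
conventionally read as strong evidence.  The neural mass model is the
nested special case of the field model with the transit time structurally
zero, so it has one fewer free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .inversion import PosteriorDensity
from .model_core import ModelParams

#: log-evidence difference conventionally read as strong evidence
STRONG_EVIDENCE: float = 3.0


def make_mass_variant(params: ModelParams) -> ModelParams:
    """Neural mass homologue of a field parameter set.

    Sets the structural mass-limit flag (effective transit time exactly
    zero); in inversion the transit time is also dropped from the
    estimated parameters (see ``ParameterMap.for_variant``), so the
    variant has one fewer free parameter.  An alternative, faithful to
    treating the mass model as a prior constraint, is a very precise
    shrinkage prior on the transit-time scaling
    (``PriorDensity.shrink(pmap, "upsilon")``); the structural route is
    the default because a log-scaled parameter cannot reach zero exactly.
    """
    return replace(params, mass_limit=True)


@dataclass
class ComparisonTable:
    """Free energies of model variants fitted to the same data."""

    table: pd.DataFrame          # columns: model, F; sorted by F desc
    deltas: pd.DataFrame         # antisymmetric pairwise F differences
    best: str
    strong: bool                 # best beats runner-up by >= 3 nats

    def delta(self, a: str, b: str) -> float:
        """F(a) - F(b)."""
        return float(self.deltas.loc[a, b])


def compare_models(posteriors: dict[str, PosteriorDensity] |
                   list[PosteriorDensity],
                   names: list[str] | None = None) -> ComparisonTable:
    """Rank fitted variants by free energy.

    All posteriors must have been fitted to the same data (checked via the
    stored data hash).  Returns the ranked table, the antisymmetric matrix
    of pairwise log-evidence differences, and whether the winner's margin
    over the runner-up reaches the strong-evidence threshold.
    """
    if isinstance(posteriors, dict):
        items = list(posteriors.items())
    else:
        if names is None:
            names = [f"model_{i}" for i in range(len(posteriors))]
        items = list(zip(names, posteriors))
    if not items:
        raise ValueError("no posteriors to compare")
    hashes = {p.data_hash for _, p in items if p.data_hash}
    if len(hashes) > 1:
        raise ValueError("posteriors were fitted to different data")
    tbl = pd.DataFrame({"model": [n for n, _ in items],
                        "F": [p.F for _, p in items]})
    tbl = tbl.sort_values("F", ascending=False).reset_index(drop=True)
    f = tbl.set_index("model")["F"]
    deltas = pd.DataFrame(f.values[:, None] - f.values[None, :],
                          index=f.index, columns=f.index)
    best = str(tbl.loc[0, "model"])
    strong = bool(len(tbl) > 1
                  and tbl.loc[0, "F"] - tbl.loc[1, "F"] >= STRONG_EVIDENCE)
    return ComparisonTable(table=tbl, deltas=deltas, best=best,
                           strong=strong)
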