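"""The n-star quality consensus over N classifier votes.

Given N classifiers of one family (here: the fold models of a cross-validated
training run), the n-star consensus C_n^N labels a residue positive iff at
least n of the N classifiers vote positive. Raising n raises the consensus
quality demanded of a positive call: the 1-star positive set is the union of
the individual positive sets, the N-star set their intersection, and the sets
are nested in between, so recall can only fall (and false positives only
shrink) as n grows.

Votes are hard labels. Positions a model abstains on (U — window does not
fit) are excluded from the count; a position where all N models abstain is
reported unpredicted. Since fold models share one window width, positions in
practice abstain all-or-none.
"""

from __future__ import annotations

import numpy as np

from .annotations import ResidueAnnotation
from .errors import ConfigError

#: Vote encoding in a vote matrix.
VOTE_POSITIVE = 1
VOTE_NEGATIVE = 0
VOTE_ABSTAIN = -1

_VOTE_LABEL = {VOTE_POSITIVE: "D", VOTE_NEGATIVE: "L", VOTE_ABSTAIN: "U"}


def validate_votes(votes: np.ndarray) -> np.ndarray:
    votes = np.asarray(votes)
    if votes.ndim != 2:
        raise ConfigError("vote matrix must be 2-D (positions x models)")
    if not np.isin(votes, (VOTE_POSITIVE, VOTE_NEGATIVE, VOTE_ABSTAIN)).all():
        raise ConfigError("votes must be in {1, 0, -1}")
    return votes.astype(int)


def n_star(votes: np.ndarray, n: int) -> np.ndarray:
    """Per-position consensus label for quality level n.

    ``votes`` has shape (L, N) over {1, 0, -1}. Returns an int array over the
    same encoding: 1 where at least n non-abstaining votes are positive, -1
    where all N models abstain, 0 otherwise.
    """
    votes = validate_votes(votes)
    n_models = votes.shape[1]
    if not 1 <= n <= n_models:
        raise ConfigError(f"n must be in [1, {n_models}], got {n}")
    positives = (votes == VOTE_POSITIVE).sum(axis=1)
    all_abstain = (votes == VOTE_ABSTAIN).all(axis=1)
    out = np.where(positives >= n, VOTE_POSITIVE, VOTE_NEGATIVE)
    out[all_abstain] = VOTE_ABSTAIN
    return out


def consensus_to_annotation(consensus: np.ndarray) -> ResidueAnnotation:
    """Render a consensus vote vector as a D/L/U annotation string."""
    return ResidueAnnotation("".join(_VOTE_LABEL[int(v)] for v in consensus))


def vote_matrix(model_set, protein, disorder=None) -> np.ndarray:
    """Per-residue votes of every fold model of a trained set, shape (L, N)."""
    columns = []
    for index in range(len(model_set.models)):
        _, votes = model_set.predict_residues(index, protein, disorder)
        columns.append(votes)
    return np.column_stack(columns)


def consensus_predict(model_set, protein, disorder=None, n: int = 2) -> ResidueAnnotation:
    """n-star consensus prediction of a trained model set on one protein."""
    if not 1 <= n <= len(model_set.models):
        raise ConfigError(
            f"n-star level {n} outside [1, {len(model_set.models)}] models"
        )
    votes = vote_matrix(model_set, protein, disorder)
    return consensus_to_annotation(n_star(votes, n))


def votes_frame(votes: np.ndarray, consensus: np.ndarray):
    """Audit table: position, one column per model, consensus label."""
    import pandas as pd

    votes = validate_votes(votes)
    data = {"position": np.arange(1, votes.shape[0] + 1)}
    for j in range(votes.shape[1]):
        data[f"model_{j}"] = [_VOTE_LABEL[int(v)] for v in votes[:, j]]
    data["consensus"] = [_VOTE_LABEL[int(v)] for v in consensus]
    return pd.DataFrame(data)
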