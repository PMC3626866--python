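"""Stoichiometric model container and reversible-reaction splitting.

A :class:`MetabolicModel` holds the N x M stoichiometric matrix ``S`` over
internal metabolites only; exchange reactions appear as single-ended columns
(the boundary side is implicit, the standard constraint-based convention).
All interfaces are keyed by string identifiers, never positional indices.

Optimization requires an irreversible network: :func:`split_reversible`
replaces each reversible reaction by a forward component (original column,
original id) and a backward component (negated column, id suffixed ``_b``),
recording the pairing in ``split_pairs`` so the optimizer can forbid
simultaneous up- (or down-) regulation of both directions of one enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError

BACKWARD_SUFFIX = "_b"


@dataclass
class MetabolicModel:
    """Stoichiometric metabolic model.

    Parameters
    ----------
    metabolite_ids : list of str
        Internal metabolites (rows of ``S``).
    reaction_ids : list of str
        Reactions (columns of ``S``).
    S : ndarray of shape (N, M)
        Stoichiometric coefficients; negative = consumed, positive = produced.
    reversible : ndarray of bool, shape (M,)
        Per-reaction reversibility flags.
    target_id : str, optional
        The engineering objective reaction (flux to maximize).
    biomass_id : str, optional
        The growth reaction, if the model has one.
    split_pairs : dict
        Forward-component id -> backward-component id; populated by
        :func:`split_reversible`, empty otherwise.
    vmax : dict
        Optional per-reaction maximal velocities (flux units), as read from
        the model file; may cover only a subset of reactions.
    units : str
        Opaque flux-unit label carried through results (e.g.
        ``nmol/10^6 cells/day``).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    reversible: np.ndarray
    target_id: str | None = None
    biomass_id: str | None = None
    split_pairs: dict[str, str] = field(default_factory=dict)
    vmax: dict[str, float] = field(default_factory=dict)
    units: str = ""

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self._index = {rid: j for j, rid in enumerate(self.reaction_ids)}
        self.validate()

    # -- basics ---------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def index(self, reaction_id: str) -> int:
        """Column index of ``reaction_id`` (raises KeyError if absent)."""
        return self._index[reaction_id]

    @property
    def is_split(self) -> bool:
        """True when every reaction is irreversible."""
        return not bool(self.reversible.any())

    def validate(self) -> None:
        n, m = len(self.metabolite_ids), len(self.reaction_ids)
        if len(set(self.metabolite_ids)) != n:
            raise ValidationError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != m:
            raise ValidationError("duplicate reaction ids")
        if self.S.shape != (n, m):
            raise ValidationError(
                f"S has shape {self.S.shape}, expected ({n}, {m})"
            )
        if self.reversible.shape != (m,):
            raise ValidationError("reversible flags do not match reaction count")
        empty = [rid for j, rid in enumerate(self.reaction_ids)
                 if not np.any(self.S[:, j])]
        if empty:
            raise ValidationError(f"reactions with empty stoichiometry: {empty}")
        for name, rid in (("target", self.target_id), ("biomass", self.biomass_id)):
            if rid is not None and rid not in self._index:
                raise ValidationError(f"{name} reaction {rid!r} not in model")
        if self.split_pairs:
            fwd = list(self.split_pairs)
            bwd = list(self.split_pairs.values())
            if len(set(fwd) | set(bwd)) != len(fwd) + len(bwd):
                raise ValidationError("split_pairs is not one-to-one")
            for f, b in self.split_pairs.items():
                jf, jb = self._index.get(f), self._index.get(b)
                if jf is None or jb is None:
                    raise ValidationError(f"split pair ({f}, {b}) names unknown reactions")
                if not np.allclose(self.S[:, jb], -self.S[:, jf]):
                    raise ValidationError(
                        f"backward column of {f} is not the negated forward column")
        for rid, v in self.vmax.items():
            if rid not in self._index:
                raise ValidationError(f"vmax given for unknown reaction {rid!r}")
            if not v > 0:
                raise ValidationError(f"vmax for {rid!r} must be positive, got {v}")

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            reversible=self.reversible.copy(),
            split_pairs=dict(self.split_pairs),
            vmax=dict(self.vmax),
        )


def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Split reversible reactions into irreversible forward/backward pairs.

    The forward component keeps the original id and column; the backward
    component gets the ``_b`` suffix and the negated column, appended after
    all original columns in original order.  Idempotent on already-split
    models.  Any vmax assigned to a reversible reaction is carried to both
    directions (the same enzyme catalyses both).
    """
    if model.is_split:
        return model.copy()

    rev_idx = np.flatnonzero(model.reversible)
    backward_ids = []
    pairs = dict(model.split_pairs)
    for j in rev_idx:
        fwd = model.reaction_ids[j]
        bwd = fwd + BACKWARD_SUFFIX
        if bwd in model._index or bwd in backward_ids:
            raise ValidationError(
                f"cannot split {fwd!r}: id {bwd!r} already exists")
        backward_ids.append(bwd)
        pairs[fwd] = bwd

    S_new = np.hstack([model.S, -model.S[:, rev_idx]])
    vmax = dict(model.vmax)
    for j, bwd in zip(rev_idx, backward_ids):
        fwd = model.reaction_ids[j]
        if fwd in vmax:
            vmax[bwd] = vmax[fwd]

    return MetabolicModel(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=list(model.reaction_ids) + backward_ids,
        S=S_new,
        reversible=np.zeros(model.n_reactions + len(rev_idx), dtype=bool),
        target_id=model.target_id,
        biomass_id=model.biomass_id,
        split_pairs=pairs,
        vmax=vmax,
        units=model.units,
    )
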