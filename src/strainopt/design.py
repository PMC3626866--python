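"""High-level Model/Results surface for strain design.

``StrainDesign`` bundles a split metabolic model, its reference state and a
capacity table; ``fit()`` solves the chosen design problem and returns a
``StrainDesignResults`` that carries the intervention set, the predicted
target flux and diagnostics, knows how to ``summary()`` itself, and can
``evaluate()`` its own design by Monte-Carlo FBA.

    >>> design = StrainDesign(model, ref, caps)
    >>> res = design.fit(method="ccopt", eps=0.25, L=2)
    >>> print(res.summary())
    >>> ev = res.evaluate(n_samples=10_000, seed=7)
"""

from __future__ import annotations

from dataclasses import replace

from .capacity import CapacityTable, ReferenceState
from .evaluate import EvalDistribution, mceval_run
from .model import MetabolicModel, split_reversible
from .optimize import (InterventionSet, OptimizationResult,
                       OptimizationSettings, ccopt_solve, detopt_solve,
                       mcopt_run)

__all__ = ["StrainDesign", "StrainDesignResults"]


class StrainDesign:
    """Strain-design problem over a metabolic model.

    Parameters
    ----------
    model : MetabolicModel
        Will be split into irreversible components if needed.
    ref : ReferenceState
        Reference-state bounds aligned with the *split* model.
    caps : CapacityTable
        Capacity distributions for the candidate reactions.
    settings : OptimizationSettings, optional
        Defaults for fit(); individual fit() keywords override them.
    """

    def __init__(self, model: MetabolicModel, ref: ReferenceState,
                 caps: CapacityTable,
                 settings: OptimizationSettings | None = None):
        self.model = model if model.is_split else split_reversible(model)
        self.ref = ref
        self.caps = caps
        self.settings = settings or OptimizationSettings()

    def _settings(self, **overrides) -> OptimizationSettings:
        overrides = {k: v for k, v in overrides.items() if v is not None}
        return replace(self.settings, **overrides) if overrides else self.settings

    def fit(self, method: str = "ccopt", eps: float | None = None,
            L: int | None = None, alpha: float | None = None,
            **kwargs) -> "StrainDesignResults":
        """Solve the design MILP.  ``method`` is 'ccopt' or 'detopt'."""
        settings = self._settings(eps=eps, L=L, alpha=alpha, **kwargs)
        if method == "ccopt":
            result = ccopt_solve(self.model, self.ref, self.caps, settings)
        elif method == "detopt":
            result = detopt_solve(self.model, self.ref, self.caps, settings)
        else:
            raise ValueError(f"unknown method {method!r} (use 'ccopt' or 'detopt')")
        return StrainDesignResults(self, result, method)

    def fit_montecarlo(self, n_samples: int, seed: int,
                       **overrides):
        """MCOpt: repeated MILP over sampled capacities.

        Returns ``(runs, frequencies)`` as :func:`strainopt.optimize.mcopt_run`.
        """
        settings = self._settings(**overrides)
        return mcopt_run(self.model, self.ref, self.caps, settings,
                         n_samples, seed)

    def evaluate(self, interventions: InterventionSet, n_samples: int,
                 seed: int) -> EvalDistribution:
        """MCEval of an arbitrary intervention set."""
        return mceval_run(self.model, self.ref, self.caps, interventions,
                          n_samples, seed,
                          biomass_fraction=self.settings.biomass_fraction)


class StrainDesignResults:
    """Fitted design: intervention set, predicted flux, diagnostics."""

    def __init__(self, design: StrainDesign, result: OptimizationResult,
                 method: str):
        self.design = design
        self.result = result
        self.method = method

    @property
    def interventions(self) -> InterventionSet:
        return self.result.interventions

    @property
    def v_target(self) -> float:
        return self.result.v_target

    @property
    def objective(self) -> float:
        return self.result.objective

    @property
    def fluxes(self):
        return self.result.fluxes

    @property
    def status(self) -> str:
        return self.result.status

    def evaluate(self, n_samples: int = 10_000, seed: int = 0) -> EvalDistribution:
        """Monte-Carlo FBA evaluation of this design's intervention set."""
        return mceval_run(self.design.model, self.design.ref, self.design.caps,
                          self.interventions, n_samples, seed,
                          biomass_fraction=self.result.settings.biomass_fraction)

    def summary(self) -> str:
        header = f"Strain design ({self.method})"
        body = self.result.summary().splitlines()[2:]
        units = self.design.model.units
        lines = [header, "=" * max(34, len(header))] + body
        if units:
            lines.append(f"flux units        : {units}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<StrainDesignResults {self.method} status={self.status} "
                f"v_target={self.v_target:.4g} interventions={self.interventions}>")
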