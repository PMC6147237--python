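"""Metabolic control analysis: scaled concentration control coefficients.

``C[j, s] = d ln S_s* / d ln k_j`` measures the relative steady-state shift
of observable species *s* under a relative perturbation of reaction *j*'s
rate. For mass action, scaling the rate constant scales the local rate, so
these are the scaled concentration control coefficients; they obey the
summation theorem (each column sums to zero, because scaling *all* rates
together only rescales time).

Coefficients are estimated by central finite differences on the log scale:
each rate constant is scaled geometrically by (1+δ) and 1/(1+δ) — symmetric
spacing in ln k, so the estimate is genuinely second-order accurate — and
the steady state is re-solved from the unperturbed state (which preserves
the conserved-moiety totals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import SteadyStateConfig, SteadyStateError, find_steady_state, mass_action_flux

__all__ = ["ControlCoefficientMatrix", "control_coefficients", "rank_sensitive_reactions"]


@dataclass
class ControlCoefficientMatrix:
    """Reactions × observables matrix of scaled concentration control
    coefficients, with the perturbation fraction used and per-entry flags
    (``zero_flux`` entries are defined as 0; failed perturbed solves are
    NaN, never silently zeroed)."""

    matrix: pd.DataFrame           # index = reaction ids, columns = observable ids
    delta: float
    flags: dict = field(default_factory=dict)   # (reaction, observable) -> reason

    @property
    def reaction_ids(self):
        return list(self.matrix.index)

    @property
    def observable_ids(self):
        return list(self.matrix.columns)

    def normalized(self):
        """Per-column |C|/max|C| variant (the "fraction of maximum
        sensitivity" scale)."""
        m = self.matrix.abs()
        return m / m.max(axis=0)

    def column_sums(self):
        return self.matrix.sum(axis=0)

    def to_csv(self, path):
        self.matrix.to_csv(path, index_label="reaction")


def control_coefficients(network, steady_state, observables, delta=0.01, ss_config=None):
    """Scaled concentration control coefficients by central differences.

    Parameters
    ----------
    steady_state : NetworkState
        Verified steady state of ``network`` (residual below tolerance);
        also the warm start for every perturbed solve.
    observables : sequence of str
        Unclamped species with positive steady-state amount (a zero amount
        makes the log-derivative undefined and raises).
    delta : float
        Perturbation fraction in (0, 0.1].
    """
    if not 0 < delta <= 0.1:
        raise ValueError("delta must be in (0, 0.1]")
    cfg = ss_config or SteadyStateConfig()
    obs = list(observables)
    oidx = []
    for o in obs:
        i = network.species_index[o]
        if network.species[i].clamped:
            raise ValueError(f"observable {o!r} is clamped")
        if steady_state.amounts[i] <= 0:
            raise ValueError(f"observable {o!r} has zero steady-state amount; "
                             "log sensitivity undefined")
        oidx.append(i)
    base_res = cfg.residual_tol * 100
    from .network import _residual  # local import to avoid public surface
    if _residual(network, steady_state.amounts) > base_res:
        raise ValueError("steady_state is not converged to tolerance; "
                         "run find_steady_state first")

    flux = mass_action_flux(network, steady_state)
    dlog = 2.0 * np.log1p(delta)
    C = np.zeros((network.n_reactions, len(obs)))
    flags = {}
    for j, rx in enumerate(network.reactions):
        if flux[j] == 0.0:
            for o in obs:
                flags[(rx.id, o)] = "zero_flux"
            continue
        vals = []
        failed = None
        for fac in (1.0 + delta, 1.0 / (1.0 + delta)):
            pert = network.with_rate(rx.id, rx.rate_constant * fac)
            try:
                ss = find_steady_state(pert, steady_state, cfg)
                vals.append(np.log(ss.amounts[oidx]))
            except SteadyStateError as e:
                failed = str(e)
                break
        if failed is not None:
            C[j, :] = np.nan
            for o in obs:
                flags[(rx.id, o)] = f"perturbed steady state failed: {failed}"
            continue
        C[j, :] = (vals[0] - vals[1]) / dlog
    df = pd.DataFrame(C, index=[r.id for r in network.reactions], columns=obs)
    return ControlCoefficientMatrix(matrix=df, delta=delta, flags=flags)


def rank_sensitive_reactions(C, observable, exclude_direct=False, direct_reactions=None):
    """Reactions ordered by |C| on one observable, as fractions of the
    column maximum.

    ``exclude_direct`` removes the observable's own transcription/basal/
    decay reactions so upstream signalling events surface. For reporter
    observables named ``Luc_<factor>`` the direct set defaults to
    ``tx_/basal_/dec_<factor>``; pass ``direct_reactions`` explicitly for
    any other convention. Ties keep the network's reaction order (the sort
    is stable).
    """
    if observable not in C.matrix.columns:
        raise KeyError(f"observable {observable!r} not in the coefficient matrix")
    col = C.matrix[observable].abs()
    if exclude_direct:
        if direct_reactions is None:
            if not observable.startswith("Luc_"):
                raise ValueError("cannot infer direct reactions for "
                                 f"{observable!r}; pass direct_reactions")
            f = observable[len("Luc_"):]
            direct_reactions = (f"tx_{f}", f"basal_{f}", f"dec_{f}")
        col = col.drop(index=[r for r in direct_reactions if r in col.index])
    col = col.dropna()
    if col.empty or col.max() == 0:
        raise ValueError(f"column {observable!r} is empty or identically zero")
    frac = col / col.max()
    order = np.argsort(-frac.to_numpy(), kind="stable")
    return [(frac.index[i], float(frac.iloc[i])) for i in order]
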