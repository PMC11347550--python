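"""Negative log Cox partial likelihood as a differentiable training loss.

For scores s (log relative hazards), observed times t and event indicators d, the
loss is

    L(s) = -(1/D) * sum_{i: d_i=1} [ s_i - log sum_{j: t_j >= t_i} exp(s_j) ]

with D the number of events. Tied event times use the Breslow convention (all
subjects with t_j >= t_i, ties included, share one risk-set denominator).
Normalizing by the event count keeps learning rates comparable across cohort
sizes. The loss is invariant to adding a constant to every score.
"""

from __future__ import annotations

import numpy as np


class ZeroEventsError(ValueError):
    """The partial likelihood is undefined without at least one event."""


def _prepare(scores, times, events):
    s = np.asarray(scores, dtype=float).ravel()
    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events).ravel().astype(int)
    if not (len(s) == len(t) == len(e)) or len(s) < 2:
        raise ValueError("scores, times, events must have equal length >= 2")
    if e.sum() == 0:
        raise ZeroEventsError("no events in batch; partial likelihood undefined")
    return s, t, e


def cox_partial_likelihood_loss(scores, times, events, *, return_grad: bool = False):
    """Event-normalized negative log partial likelihood (Breslow ties).

    Parameters
    ----------
    scores, times, events:
        Equal-length vectors; events are 0/1 with at least one 1.
    return_grad:
        If True, also return dL/dscores (same shape as ``scores``).
    """
    s, t, e = _prepare(scores, times, events)
    n = len(s)
    order = np.argsort(t, kind="stable")
    s_o, t_o, e_o = s[order], t[order], e[order]

    # log-sum-exp of scores over each suffix (risk set of the slowest tie group)
    smax = s_o.max()
    rev_cum = np.cumsum(np.exp(s_o - smax)[::-1])[::-1]
    suffix_lse = smax + np.log(rev_cum)

    # first index of each tie group; every member shares the group's denominator
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = t_o[1:] != t_o[:-1]
    group_id = np.cumsum(new_group) - 1
    group_start = np.flatnonzero(new_group)
    denom = suffix_lse[group_start][group_id]

    D = e.sum()
    loss = -np.sum(e_o * (s_o - denom)) / D

    if not return_grad:
        return float(loss)

    # grad_k = -(1/D) [ e_k - exp(s_k) * sum_{groups g: t_g <= t_k} m_g / S_g ]
    n_groups = len(group_start)
    m_g = np.bincount(group_id, weights=e_o, minlength=n_groups)
    S_g = np.exp(suffix_lse[group_start])
    cum_w = np.cumsum(m_g / S_g)
    w = cum_w[group_id]
    grad_o = -(e_o - np.exp(s_o) * w) / D
    grad = np.empty(n)
    grad[order] = grad_o
    return float(loss), grad
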