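"""Exhaustive-enumeration oracle for the branch-site likelihood.

Computes the per-site likelihood by summing over *all* joint assignments of
codon states to the internal nodes — completely independent of the pruning
recursion, the site-pattern compression and the per-node rescaling of the
fast implementation.  The per-branch transition matrices are taken as given
(built through the public ``transition_matrix`` API); their own correctness
is checked separately against ``scipy.linalg.expm``.  Feasible only for tiny
trees (<= 3 internal nodes); used as the ground truth the fast
implementation must reproduce to near machine precision.
"""

import math

import numpy as np

from symscreen.codon_evolution import (
    STANDARD_CODE,
    build_rate_matrix,
    substitution_rate,
    transition_matrix,
)


def _axis_view(vec_or_mat, axes, k):
    """Reshape a vector (1 axis) or matrix (2 axes) onto the given axes of k."""
    shape = [1] * k
    if len(axes) == 1:
        shape[axes[0]] = vec_or_mat.shape[0]
        return vec_or_mat.reshape(shape)
    shape[axes[0]] = vec_or_mat.shape[0]
    shape[axes[1]] = vec_or_mat.shape[1]
    # place rows on axes[0], columns on axes[1]
    order = np.argsort([axes[0], axes[1]])
    mat = vec_or_mat if order[0] == 0 else vec_or_mat.T
    return mat.reshape(shape)


def loglik_by_enumeration(aln, tree, params, model):
    """Mixture log-likelihood by explicit summation over internal states."""
    weights, bg, fg = params.site_classes(model)
    pi = params.pi
    n = pi.shape[0]

    internals = [node for node in tree.postorder() if not node.is_leaf]
    k = len(internals)
    assert k <= 3, "enumeration oracle limited to 3 internal nodes"
    axis = {id(node): i for i, node in enumerate(internals)}
    root = internals[-1]

    # shared branch-length scale, as the model defines it
    rates = {}
    for w in set(bg) | set(fg):
        rates[w] = substitution_rate(build_rate_matrix(params.kappa, w, pi), pi)
    scale = sum(wt * rates[w] for wt, w in zip(weights, bg))

    # transition matrix per (class, branch)
    mats = {}
    for ci, (w_bg, w_fg) in enumerate(zip(bg, fg)):
        for node in tree.postorder():
            if node.parent is None:
                continue
            w = w_fg if node.foreground else w_bg
            mats[(ci, id(node))] = transition_matrix(
                params.kappa, w, pi, node.length, scale=scale
            )

    order = sorted(aln.ids)
    codes = aln.index_matrix(order)
    tip_row = {label: r for r, label in enumerate(order)}

    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for ci in range(len(weights)):
            arr = _axis_view(pi, [axis[id(root)]], k) * np.ones((n,) * k)
            for node in tree.postorder():
                if node.parent is None:
                    continue
                p = mats[(ci, id(node))]
                pa = axis[id(node.parent)]
                if node.is_leaf:
                    obs = codes[tip_row[node.label], site]
                    if obs < 0:
                        continue  # gap: partial of ones, sums P rows to 1
                    arr = arr * _axis_view(p[:, obs], [pa], k)
                else:
                    arr = arr * _axis_view(p, [pa, axis[id(node)]], k)
            site_lik += weights[ci] * float(arr.sum())
        total += math.log(site_lik)
    return total


def random_small_params(rng, model):
    """Random but well-conditioned parameter draw for the oracle sweep."""
    from symscreen.codon_evolution import BranchSiteParams

    dirichlet = rng.dirichlet(np.full(61, 5.0))
    pi = 0.5 * dirichlet + 0.5 / 61  # keep frequencies away from zero
    p0, p1 = rng.dirichlet([4.0, 3.0, 2.0])[:2]
    return BranchSiteParams(
        kappa=float(rng.uniform(0.5, 6.0)),
        omega0=float(rng.uniform(0.02, 0.9)),
        p0=float(p0),
        p1=float(p1),
        omega2=1.0 if model != "bs_alt" else float(rng.uniform(1.0, 20.0)),
        pi=pi,
    )


def random_small_alignment(rng, labels, n_codons, gap_rate=0.1):
    """Random codon alignment (indices drawn uniformly; some gap codons)."""
    from symscreen.codon_evolution import CodonAlignment

    rows = {}
    for label in labels:
        codons = []
        for _ in range(n_codons):
            if rng.random() < gap_rate:
                codons.append("---")
            else:
                codons.append(STANDARD_CODE.sense_codons[rng.integers(61)])
        rows[label] = "".join(codons)
    return CodonAlignment(rows)
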