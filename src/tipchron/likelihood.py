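"""Felsenstein pruning likelihood for time trees under HKY+Gamma.

Site patterns are compressed once per alignment; per-pattern partial
likelihoods are propagated root-ward with per-pattern rescaling, so the
computation stays stable for mitogenome-length (>= 10 kb) alignments.
Ambiguity codes (and ``N``/``-``) contribute partial likelihood 1 over
every state they are compatible with.  The inner pruning recursion is
JIT-compiled (numba) because it sits on the MCMC hot path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .alignment import AMBIGUITY, Alignment
from .errors import ParameterError, TreeConstraintError
from .substitution import STATES, SubstitutionModel
from .trees import TimeTree

#: character -> 0/1 compatibility vector over (A, C, G, T)
CHAR_PARTIALS = {
    char: np.array([1.0 if STATES[i] in bases else 0.0 for i in range(4)])
    for char, bases in AMBIGUITY.items()
}
_CODES = sorted(CHAR_PARTIALS)
_CODE_INDEX = {c: i for i, c in enumerate(_CODES)}
_CODE_PARTIALS = np.stack([CHAR_PARTIALS[c] for c in _CODES])


def compress_patterns(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Collapse alignment columns into unique site patterns.

    Returns ``(codes, weights)`` where ``codes`` is an (n_taxa, n_patterns)
    integer matrix indexing into the ambiguity-code partial table and
    ``weights`` counts how many columns each pattern represents.
    """
    mat = np.empty((aln.n_taxa, aln.length), dtype=np.int8)
    for i, seq in enumerate(aln.sequences):
        mat[i] = [_CODE_INDEX[c] for c in seq]
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return patterns, weights.astype(float)


@njit(cache=True)
def _hky_kernel(t_flat, pi, kappa, out):  # pragma: no cover
    """Closed-form HKY P(t) for a flat vector of branch lengths."""
    pi_a, pi_c, pi_g, pi_t = pi[0], pi[1], pi[2], pi[3]
    pi_r = pi_a + pi_g
    pi_y = pi_c + pi_t
    beta = 1.0 / (2.0 * (pi_r * pi_y + kappa * (pi_a * pi_g + pi_c * pi_t)))
    alpha = kappa * beta
    purine = (True, False, True, False)
    for m in range(t_flat.shape[0]):
        t = t_flat[m]
        e2 = np.exp(-beta * t)
        e_r = np.exp(-(pi_r * alpha + pi_y * beta) * t)
        e_y = np.exp(-(pi_y * alpha + pi_r * beta) * t)
        for i in range(4):
            for j in range(4):
                if purine[i] != purine[j]:
                    out[m, i, j] = pi[j] * (1.0 - e2)
                elif purine[j]:
                    diag = pi_r if i == j else 0.0
                    out[m, i, j] = pi[j] + pi[j] * (pi_y / pi_r) * e2 + ((diag - pi[j]) / pi_r) * e_r
                else:
                    diag = pi_y if i == j else 0.0
                    out[m, i, j] = pi[j] + pi[j] * (pi_r / pi_y) * e2 + ((diag - pi[j]) / pi_y) * e_y


@njit(cache=True)
def _prune_kernel(order, child1, child2, pmats, partials, scale_log):  # pragma: no cover
    """Post-order partial-likelihood propagation with per-pattern rescaling.

    ``order`` lists internal node indices children-first; ``partials`` is
    (n_nodes, n_cat, n_pat, 4) with tip rows prefilled; ``pmats`` is
    (n_nodes, n_cat, 4, 4) with entry [i, j] = P(child state j | parent i).
    """
    n_cat = partials.shape[1]
    n_pat = partials.shape[2]
    for w in range(order.shape[0]):
        v = order[w]
        a = child1[w]
        b = child2[w]
        for c in range(n_cat):
            pa = pmats[a, c]
            pb = pmats[b, c]
            for p in range(n_pat):
                for i in range(4):
                    sa = 0.0
                    sb = 0.0
                    for j in range(4):
                        sa += pa[i, j] * partials[a, c, p, j]
                        sb += pb[i, j] * partials[b, c, p, j]
                    partials[v, c, p, i] = sa * sb
        for p in range(n_pat):
            m = 0.0
            for c in range(n_cat):
                for i in range(4):
                    if partials[v, c, p, i] > m:
                        m = partials[v, c, p, i]
            if m > 0.0 and (m < 1e-40 or m > 1e40):
                for c in range(n_cat):
                    for i in range(4):
                        partials[v, c, p, i] /= m
                scale_log[p] += np.log(m)


class PruningLikelihood:
    """Reusable likelihood engine bound to one alignment and site model.

    The per-tip partial-likelihood tables are precomputed; :meth:`loglik`
    then evaluates any time tree over the same taxa at a given strict-clock
    rate.  This is the hot path of the MCMC sampler.
    """

    def __init__(self, aln: Alignment, model: SubstitutionModel):
        self.aln = aln
        self.model = model
        self.taxa = list(aln.taxa)
        codes, self.weights = compress_patterns(aln)
        self.n_patterns = codes.shape[1]
        # tip partials: (n_tips, n_patterns, 4)
        self.tip_partials = _CODE_PARTIALS[codes]
        self.cat_rates = model.category_rates
        self.freqs = model.base_freqs
        self._buffer: np.ndarray | None = None  # reused across loglik calls
        self._buffer_order: list[str] | None = None
        self._pmats: np.ndarray | None = None
        self._topo_cache: tuple | None = None  # (tree id, version) -> traversal arrays

    def loglik(self, tree: TimeTree, clock_rate: float) -> float:
        if clock_rate <= 0:
            raise ParameterError("clock rate must be > 0")
        if sorted(tree.labels) != sorted(self.taxa):
            raise ParameterError("tree tip labels do not match alignment taxa")

        ages = tree.ages
        parent = tree.parent
        n_tips = tree.n_tips
        k = len(self.cat_rates)
        n_pat = self.n_patterns

        # branch lengths in expected substitutions, per category: (node, cat)
        blen = np.zeros(len(ages))
        has_parent = parent >= 0
        blen[has_parent] = ages[parent[has_parent]] - ages[has_parent]
        if np.any(blen < 0):
            raise TreeConstraintError("child older than its parent")
        subs = blen[:, None] * clock_rate * self.cat_rates[None, :]
        if self._pmats is None or self._pmats.shape[0] != subs.size:
            self._pmats = np.empty((subs.size, 4, 4))
        _hky_kernel(subs.ravel(), self.freqs, self.model.kappa, self._pmats)
        pmats = self._pmats.reshape(len(ages), k, 4, 4)

        if self._buffer is None or self._buffer_order != tree.labels:
            self._buffer = np.empty((len(ages), k, n_pat, 4))
            for i, label in enumerate(tree.labels):
                src = self.taxa.index(label)
                self._buffer[i] = np.broadcast_to(self.tip_partials[src], (k, n_pat, 4))
            self._buffer_order = list(tree.labels)
        partials = self._buffer
        scale_log = np.zeros(n_pat)

        key = (id(tree), tree.topology_version)
        if self._topo_cache is None or self._topo_cache[0] != key:
            cm = tree.children_map()
            internal = [v for v in tree.postorder() if v >= n_tips]
            order = np.array(internal, dtype=np.int64)
            child1 = np.array([cm[v][0] for v in internal], dtype=np.int64)
            child2 = np.array([cm[v][1] for v in internal], dtype=np.int64)
            self._topo_cache = (key, order, child1, child2, tree.root)
        _, order, child1, child2, root = self._topo_cache
        _prune_kernel(order, child1, child2, pmats, partials, scale_log)

        root_partial = partials[root]  # (cat, pat, 4)
        site_lik = (root_partial @ self.freqs).mean(axis=0)  # (pat,)
        with np.errstate(divide="ignore"):
            log_site = np.log(site_lik) + scale_log
        return float(np.dot(self.weights, log_site))


def tree_log_likelihood(aln: Alignment, tree: TimeTree, clock_rate: float,
                        model: SubstitutionModel) -> float:
    """Log-likelihood of ``aln`` on ``tree`` under a strict clock.

    Branch substitution lengths are ``(parent age - child age) * clock_rate``;
    the likelihood is summed over sites and discrete-gamma categories.
    """
    return PruningLikelihood(aln, model).loglik(tree, clock_rate)
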