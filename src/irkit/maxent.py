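"""Maximum-entropy models of splice-site strength.

A splice site is a fixed-width window (donor: 3 exonic + 6 intronic nt;
acceptor: 20 intronic + 3 exonic nt). The model is the maximum-entropy
distribution over windows subject to empirical marginal constraints on
position subsets (all singletons plus adjacent and skip-one pairs by
default), fit by generalized iterative scaling. Because full enumeration
is infeasible at acceptor width (4^23 outcomes), inference is exact
sum-product over the junction-tree clique chain {i, i+1, i+2} that the
default constraint set induces. Site strength is the log2-odds of the
window under the model versus an order-0 background composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import mannwhitneyu

DNA = "ACGT"

DONOR_WIDTH = 9  # exon -3..-1 + intron +1..+6
ACCEPTOR_WIDTH = 23  # intron -20..-1 + exon +1..+3

# Maximum constraint span supported by the clique-chain inference
_MAX_SPAN = 2


def default_constraints(width: int) -> list[tuple[int, ...]]:
    """All singletons + adjacent + skip-one pairwise position subsets."""
    cons: list[tuple[int, ...]] = [(i,) for i in range(width)]
    cons += [(i, i + 1) for i in range(width - 1)]
    cons += [(i, i + 2) for i in range(width - 2)]
    return cons


def order1_constraints(width: int) -> list[tuple[int, ...]]:
    return [(i,) for i in range(width)]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class MaxEntModel:
    kind: str
    width: int
    alphabet: str
    constraints: list[tuple[int, ...]]
    lambdas: dict[tuple[int, ...], np.ndarray]
    background: np.ndarray
    trained_on: int = 0
    n_iter: int = 0
    max_deviation: float = float("nan")

    # -- probability queries ------------------------------------------------

    def _chain(self) -> "_CliqueChain":
        return _CliqueChain(self.width, len(self.alphabet), self.constraints, self.lambdas)

    def log_prob(self, windows) -> np.ndarray:
        """Natural-log model probability of each window."""
        chain = self._chain()
        enc = _encode(windows, self.alphabet)
        lp = np.zeros(enc.shape[0])
        for c, pos in enumerate(chain.cliques):
            psi = chain.psi[c]
            idx = tuple(enc[:, p] for p in pos)
            lp += psi[idx]
        return lp - chain.log_z()

    def score(self, windows, background=None) -> np.ndarray:
        """Site strength in bits: log2 P_model(x) / P_background(x)."""
        bg = np.asarray(self.background if background is None else background, float)
        enc = _encode(windows, self.alphabet)
        log_bg = np.log(bg)[enc].sum(axis=1)
        return (self.log_prob(windows) - log_bg) / np.log(2.0)

    def marginals(self) -> dict[tuple[int, ...], np.ndarray]:
        return self._chain().constraint_marginals()

    def enumerate_probs(self) -> np.ndarray:
        """Full probability table, outcomes in odometer order (small widths only)."""
        a = len(self.alphabet)
        if a**self.width > 2_000_000:
            raise ValueError("sequence space too large to enumerate")
        grids = np.indices((a,) * self.width).reshape(self.width, -1).T
        seqs = ["".join(self.alphabet[i] for i in row) for row in grids]
        return np.exp(self.log_prob(seqs))

    def entropy(self) -> float:
        p = self.enumerate_probs()
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    def sample(self, n: int, rng: np.random.Generator) -> list[str]:
        """Exact forward sampling along the clique chain."""
        chain = self._chain()
        mus = chain.clique_marginals()
        a = chain.a
        out = np.empty((n, self.width), dtype=np.int64)
        # first clique: joint sample over its positions
        mu0 = mus[0].reshape(-1)
        first = rng.choice(mu0.size, size=n, p=mu0 / mu0.sum())
        k0 = len(chain.cliques[0])
        for j in range(k0 - 1, -1, -1):
            out[:, chain.cliques[0][j]] = first % a
            first //= a
        for c in range(1, len(chain.cliques)):
            pos = chain.cliques[c]
            mu = mus[c]  # shape (a, a, a) over (i, i+1, i+2)
            cond = mu / mu.sum(axis=2, keepdims=True).clip(min=1e-300)
            prev = (out[:, pos[0]], out[:, pos[1]])
            u = rng.random(n)
            cdf = np.cumsum(cond[prev[0], prev[1], :], axis=1)
            out[:, pos[2]] = (u[:, None] > cdf).sum(axis=1)
        return ["".join(self.alphabet[i] for i in row) for row in out]

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            "kind": self.kind,
            "width": self.width,
            "alphabet": self.alphabet,
            "constraints": [list(c) for c in self.constraints],
            "lambdas": {
                ",".join(map(str, k)): v.tolist() for k, v in self.lambdas.items()
            },
            "background": self.background.tolist(),
            "trained_on": self.trained_on,
            "n_iter": self.n_iter,
            "max_deviation": self.max_deviation,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MaxEntModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            kind=doc["kind"],
            width=doc["width"],
            alphabet=doc["alphabet"],
            constraints=[tuple(c) for c in doc["constraints"]],
            lambdas={
                tuple(int(x) for x in k.split(",")): np.asarray(v)
                for k, v in doc["lambdas"].items()
            },
            background=np.asarray(doc["background"]),
            trained_on=doc["trained_on"],
            n_iter=doc["n_iter"],
            max_deviation=doc["max_deviation"],
        )


# ---------------------------------------------------------------------------
# Exact inference on the clique chain
# ---------------------------------------------------------------------------


def _encode(windows, alphabet: str) -> np.ndarray:
    lut = {ch: i for i, ch in enumerate(alphabet)}
    return np.asarray([[lut[ch] for ch in w] for w in windows], dtype=np.int64)


class _CliqueChain:
    """Sum-product over cliques (i, i+1, i+2); supports width < 3 as one clique."""

    def __init__(self, width, a, constraints, lambdas):
        self.width = width
        self.a = a
        if width <= _MAX_SPAN + 1:
            self.cliques = [tuple(range(width))]
        else:
            self.cliques = [(i, i + 1, i + 2) for i in range(width - 2)]
        for c in constraints:
            if max(c) - min(c) > _MAX_SPAN:
                raise ValueError(
                    f"constraint {c} spans more than {_MAX_SPAN} positions; "
                    "unsupported by the clique-chain inference"
                )
        self._keys = [tuple(c) for c in constraints]
        # assign each constraint factor to the clique starting at min(c)
        # (clamped to the last clique)
        self.psi = [np.zeros((a,) * len(pos)) for pos in self.cliques]
        n_cliques = len(self.cliques)
        for c in self._keys:
            lam = lambdas.get(c)
            if lam is None:
                continue
            ci = min(min(c), n_cliques - 1)
            pos = self.cliques[ci]
            axes = tuple(pos.index(p) for p in c)  # ascending: c and pos sorted
            expanded = lam
            for missing in range(len(pos)):
                if missing not in axes:
                    expanded = np.expand_dims(expanded, axis=missing)
            self.psi[ci] += expanded
        self._fwd = None
        self._bwd = None

    # messages over separators (last two positions of each clique)
    def _forward(self):
        if self._fwd is not None:
            return self._fwd
        a = self.a
        msgs = []
        prev = None
        for c, psi in enumerate(self.psi):
            if len(self.cliques) == 1:
                break
            work = psi.copy()
            if prev is not None:
                work = work + prev[:, :, None]
            msg = logsumexp(work, axis=0)  # marginalize first position
            msgs.append(msg)
            prev = msg
        self._fwd = msgs
        return msgs

    def _backward(self):
        if self._bwd is not None:
            return self._bwd
        msgs = [None] * len(self.psi)
        nxt = None
        for c in range(len(self.psi) - 1, 0, -1):
            work = self.psi[c].copy()
            if nxt is not None:
                work = work + nxt[None, :, :]
            msgs[c - 1] = logsumexp(work, axis=2)  # over last position -> (i+1, i+2)...
            nxt = msgs[c - 1]
        self._bwd = msgs
        return msgs

    def log_z(self) -> float:
        if len(self.cliques) == 1:
            return float(logsumexp(self.psi[0]))
        work = self.psi[0]
        bwd = self._backward()
        if bwd[0] is not None:
            work = work + bwd[0][None, :, :]
        return float(logsumexp(work))

    def clique_marginals(self) -> list[np.ndarray]:
        """Normalized joint distribution over each clique's positions."""
        if len(self.cliques) == 1:
            lp = self.psi[0] - logsumexp(self.psi[0])
            return [np.exp(lp)]
        fwd = self._forward()
        bwd = self._backward()
        logz = self.log_z()
        out = []
        for c, psi in enumerate(self.psi):
            work = psi.copy()
            if c > 0:
                work = work + fwd[c - 1][:, :, None]
            if bwd[c] is not None:
                work = work + bwd[c][None, :, :]
            out.append(np.exp(work - logz))
        return out

    def constraint_marginals(self) -> dict[tuple[int, ...], np.ndarray]:
        mus = self.clique_marginals()
        n_cliques = len(self.cliques)
        out: dict[tuple[int, ...], np.ndarray] = {}
        for c in self._constraint_keys():
            ci = min(min(c), n_cliques - 1)
            pos = self.cliques[ci]
            mu = mus[ci]
            keep = tuple(pos.index(p) for p in c)
            drop = tuple(i for i in range(len(pos)) if i not in keep)
            marg = mu.sum(axis=drop) if drop else mu
            if len(keep) > 1 and keep != tuple(sorted(keep)):
                marg = marg.T
            out[tuple(c)] = marg
        return out

    def _constraint_keys(self):
        return self._keys


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def empirical_marginals(
    sites, constraints, alphabet: str = DNA, pseudocount: float = 0.5
) -> dict[tuple[int, ...], np.ndarray]:
    """Smoothed empirical marginals for each constrained position subset.

    Smoothing mixes the empirical distribution with the uniform joint at a
    weight equivalent to ``pseudocount`` observations per cell of the
    largest constraint table. Mixing at the joint level (rather than
    per-table pseudocounts) keeps the marginal system consistent — the
    singleton marginals implied by the pair tables equal the singleton
    tables — which iterative scaling requires to converge.
    """
    enc = _encode(sites, alphabet)
    n = enc.shape[0]
    a = len(alphabet)
    # mass equivalent to `pseudocount` observations per cell of a pairwise
    # table, independent of the constraint set so that nested constraint
    # sets share consistent targets
    eps = pseudocount * a**2 / (n + pseudocount * a**2)
    out = {}
    for c in constraints:
        tab = np.zeros((a,) * len(c), dtype=float)
        idx = tuple(enc[:, p] for p in c)
        np.add.at(tab, idx, 1.0)
        tab /= tab.sum()
        out[tuple(c)] = (1 - eps) * tab + eps / (a ** len(c))
    return out


def train(
    sites,
    constraint_set=None,
    tol: float = 1e-4,
    max_iter: int = 500,
    pseudocount: float = 0.5,
    alphabet: str = DNA,
    kind: str = "donor",
    min_sites: int = 50,
    enforce_min_sites: bool = True,
) -> MaxEntModel:
    """Fit the maximum-entropy model by iterative proportional fitting.

    Each sweep visits every constraint and applies the full multiplicative
    update lambda_c += ln(empirical_c / model_c) with freshly computed
    model marginals (exact, via the clique chain). Sweeps repeat until
    every constrained marginal matches its empirical value within ``tol``
    (maximum absolute deviation). Deterministic; raises
    :class:`ConvergenceError` if ``max_iter`` sweeps are exhausted.
    """
    sites = list(sites)
    if enforce_min_sites and len(sites) < min_sites:
        raise ValueError(f"need >= {min_sites} sites, got {len(sites)}")
    widths = {len(s) for s in sites}
    if len(widths) != 1:
        raise ValueError("all sites must share one width")
    width = widths.pop()
    if constraint_set is None:
        constraint_set = default_constraints(width)
    constraint_set = [tuple(c) for c in constraint_set]
    emp = empirical_marginals(sites, constraint_set, alphabet, pseudocount)
    a = len(alphabet)
    lambdas = {c: np.zeros((a,) * len(c)) for c in constraint_set}
    # order-0 background from the same training sites
    enc = _encode(sites, alphabet)
    bg = np.bincount(enc.reshape(-1), minlength=a).astype(float) + pseudocount
    bg /= bg.sum()

    deviation = float("inf")
    it = 0
    for it in range(1, max_iter + 1):
        chain = _CliqueChain(width, a, constraint_set, lambdas)
        model_marg = chain.constraint_marginals()
        deviation = max(
            float(np.abs(model_marg[c] - emp[c]).max()) for c in constraint_set
        )
        if deviation <= tol:
            break
        for c in constraint_set:
            chain = _CliqueChain(width, a, constraint_set, lambdas)
            mc = chain.constraint_marginals()[c]
            lambdas[c] = lambdas[c] + np.log(emp[c].clip(1e-12) / mc.clip(1e-12))
    else:
        raise ConvergenceError(
            f"GIS did not converge in {max_iter} iterations "
            f"(max marginal deviation {deviation:.3g} > tol {tol:g})"
        )
    model = MaxEntModel(
        kind=kind,
        width=width,
        alphabet=alphabet,
        constraints=constraint_set,
        lambdas=lambdas,
        background=bg,
        trained_on=len(sites),
        n_iter=it,
        max_deviation=deviation,
    )
    return model


# ---------------------------------------------------------------------------
# Window extraction and group comparison
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def donor_window(chrom_seq: str, intron) -> str:
    """9-nt donor window (exon -3..-1 + intron +1..+6) in transcript orientation."""
    if intron.strand == "+":
        return chrom_seq[intron.start - 3 : intron.start + 6]
    return revcomp(chrom_seq[intron.end - 6 : intron.end + 3])


def acceptor_window(chrom_seq: str, intron) -> str:
    """23-nt acceptor window (intron -20..-1 + exon +1..+3)."""
    if intron.strand == "+":
        return chrom_seq[intron.end - 20 : intron.end + 3]
    return revcomp(chrom_seq[intron.start - 3 : intron.start + 20])


def pair_scores(
    introns,
    retained_ids: set,
    chrom_seqs: dict[str, str],
    donor_model: MaxEntModel,
    acceptor_model: MaxEntModel,
    n_bins: int = 100,
):
    """Donor/acceptor strength per intron + 2-D binned counts per group.

    Returns a dict with per-group score arrays, 100x100 bin counts over the
    joint (donor, acceptor) score range, mean shifts (retained - other) and
    one-sided Mann-Whitney p-values for the retained-scores-lower test.
    """
    recs = []
    for intr in introns:
        seq = chrom_seqs[intr.chrom]
        dwin = donor_window(seq, intr)
        awin = acceptor_window(seq, intr)
        if len(dwin) != donor_model.width or len(awin) != acceptor_model.width:
            continue
        if any(ch not in donor_model.alphabet for ch in dwin + awin):
            continue
        recs.append((intr.id, dwin, awin, intr.id in retained_ids))
    dscores = donor_model.score([r[1] for r in recs])
    ascores = acceptor_model.score([r[2] for r in recs])
    is_ret = np.array([r[3] for r in recs])
    out = {
        "intron_ids": [r[0] for r in recs],
        "donor_scores": dscores,
        "acceptor_scores": ascores,
        "is_retained": is_ret,
    }
    lo_d, hi_d = dscores.min(), dscores.max()
    lo_a, hi_a = ascores.min(), ascores.max()
    for label, mask in (("retained", is_ret), ("other", ~is_ret)):
        h, _, _ = np.histogram2d(
            dscores[mask],
            ascores[mask],
            bins=n_bins,
            range=[[lo_d, hi_d], [lo_a, hi_a]],
        )
        out[f"hist_{label}"] = h
    if is_ret.any() and (~is_ret).any():
        out["donor_mean_shift"] = float(
            dscores[is_ret].mean() - dscores[~is_ret].mean()
        )
        out["acceptor_mean_shift"] = float(
            ascores[is_ret].mean() - ascores[~is_ret].mean()
        )
        out["donor_p_lower"] = float(
            mannwhitneyu(dscores[is_ret], dscores[~is_ret], alternative="less").pvalue
        )
        out["acceptor_p_lower"] = float(
            mannwhitneyu(ascores[is_ret], ascores[~is_ret], alternative="less").pvalue
        )
    return out
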