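"""De novo mutational-signature extraction and reference refitting.

Extraction factorizes a catalog V (channels x samples) as V ~ W H, with W the
signature matrix (channel probabilities, columns summing to 1) and H the
exposure matrix (per-sample mutation counts attributed to each signature).
The factorization minimizes the generalized Kullback-Leibler divergence via
multiplicative updates with multiple random restarts — a maximum-likelihood
counterpart of the Bayesian samplers commonly used for this task, chosen here
for determinism and speed.  Model order (the number of signatures K) is
selected from a goodness-of-fit curve of mean per-sample reconstruction
cosine similarity, taking the last K whose gain over K-1 exceeds an elbow
threshold.

Refitting against a fixed reference signature set uses expectation-
maximization under the same KL objective, followed by a prune-and-refit
rule: signatures attributed <= 5% of a sample's mutations are dropped and
the remaining set refitted, iterated to a fixed point; among all candidate
sets visited, the one whose reconstruction has the highest cosine similarity
to the observed spectrum is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ucsomatic.catalogs import MutationCatalog, _SCHEME_CHANNELS

__all__ = [
    "SignatureMatrix",
    "extract_signatures",
    "goodness_of_fit",
    "fit_exposures",
    "reconstruct_spectrum",
    "cosine_similarity",
    "match_reference",
    "flag_mmr_deficiency",
    "DEFAULT_MMR_SIGNATURES",
]

_EPS = 1e-12

#: reference signatures conventionally associated with defective mismatch repair
DEFAULT_MMR_SIGNATURES = frozenset({"SBS6", "SBS15", "SBS20", "SBS21", "SBS26", "SBS44"})


@dataclass
class SignatureMatrix:
    """Named signature columns of channel probabilities (each summing to 1)."""

    data: pd.DataFrame
    scheme: str | None = None

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = arr.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"signature columns must sum to 1, got {sums}")
        if self.scheme is not None:
            expected = list(_SCHEME_CHANNELS[self.scheme])
            if list(self.data.index) != expected:
                self.data = self.data.reindex(expected)
                if self.data.isna().any().any():
                    raise ValueError(f"signature channels do not match scheme {self.scheme}")

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_signatures(self) -> int:
        return self.data.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def from_tsv(cls, path, scheme: str | None = None) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df / df.sum(axis=0)
        return cls(data=df, scheme=scheme)


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two spectra; errors on zero vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def _gkl(V: np.ndarray, R: np.ndarray) -> float:
    """Generalized KL divergence D(V || R)."""
    R = np.maximum(R, _EPS)
    mask = V > 0
    return float(np.sum(V[mask] * np.log(V[mask] / R[mask])) - V.sum() + R.sum())


def _mu_kl_nmf(
    V: np.ndarray, K: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """One run of multiplicative-update NMF under generalized KL."""
    F, N = V.shape
    scale = V.mean() / K
    W = rng.random((F, K)) + 0.1
    W /= W.sum(axis=0, keepdims=True)
    H = (rng.random((K, N)) + 0.1) * scale * K / 1.0
    prev = np.inf
    ones = np.ones_like(V)
    for it in range(max_iter):
        R = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / R)) / np.maximum(W.T @ ones, _EPS)
        R = np.maximum(W @ H, _EPS)
        W *= ((V / R) @ H.T) / np.maximum(ones @ H.T, _EPS)
        # renormalize signature columns, compensating in H
        col = W.sum(axis=0)
        col = np.maximum(col, _EPS)
        W /= col
        H *= col[:, None]
        if it % 10 == 9 or it == max_iter - 1:
            loss = _gkl(V, W @ H)
            if np.isfinite(prev) and abs(prev - loss) <= tol * max(1.0, abs(loss)):
                prev = loss
                break
            prev = loss
    return W, H, _gkl(V, W @ H)


def extract_signatures(
    catalog: MutationCatalog,
    K: int,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> tuple[SignatureMatrix, pd.DataFrame, dict]:
    """De novo extraction of K signatures from a catalog by KL-NMF.

    Returns ``(signatures, exposures, diagnostics)``: exposures is a
    samples x K DataFrame of mutation counts; diagnostics carries the best
    KL divergence, per-restart losses, and per-sample reconstruction cosine.
    """
    V = catalog.counts.to_numpy(dtype=float)
    F, N = V.shape
    if not (1 <= K <= min(N, F)):
        raise ValueError(f"K={K} out of range [1, {min(N, F)}]")
    if V.sum() <= 0:
        raise ValueError("all-zero catalog")
    ss = np.random.SeedSequence(seed)
    best = None
    losses = []
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        W, H, loss = _mu_kl_nmf(V, K, rng, max_iter, tol)
        losses.append(loss)
        if best is None or loss < best[2]:
            best = (W, H, loss)
    W, H, loss = best
    # order signatures by total attributed mutations, largest first
    order = np.argsort(-H.sum(axis=1))
    W, H = W[:, order], H[order, :]
    names = [f"S{i + 1}" for i in range(K)]
    sig = SignatureMatrix(
        data=pd.DataFrame(W, index=catalog.channels, columns=names), scheme=catalog.scheme
    )
    exposures = pd.DataFrame(H.T, index=catalog.sample_ids, columns=names)
    recon = W @ H
    per_sample = {}
    for j, s in enumerate(catalog.sample_ids):
        if V[:, j].sum() > 0:
            per_sample[s] = cosine_similarity(V[:, j], recon[:, j])
        else:
            per_sample[s] = float("nan")
    diagnostics = {
        "kl": loss,
        "restart_losses": losses,
        "reconstruction_cosine": per_sample,
        "mean_cosine": float(np.nanmean(list(per_sample.values()))),
    }
    return sig, exposures, diagnostics


def goodness_of_fit(
    catalog: MutationCatalog,
    K_range,
    n_restarts: int = 10,
    seed: int = 0,
    elbow_threshold: float = 0.01,
    **kwargs,
) -> tuple[pd.DataFrame, int]:
    """Goodness-of-fit curve over K and elbow-selected model order.

    For each K the mean per-sample reconstruction cosine is computed; the
    selected K is the last one whose gain over K-1 is at least
    ``elbow_threshold`` (the curve is non-decreasing up to restart noise, so
    this is the elbow of the plot).
    """
    Ks = sorted(K_range)
    rows = []
    scores = {}
    for K in Ks:
        _, _, diag = extract_signatures(catalog, K, n_restarts=n_restarts, seed=seed, **kwargs)
        scores[K] = diag["mean_cosine"]
        rows.append({"K": K, "mean_cosine": diag["mean_cosine"], "kl": diag["kl"]})
    selected = Ks[0]
    for prev, K in zip(Ks, Ks[1:]):
        if scores[K] - scores[prev] >= elbow_threshold:
            selected = K
        else:
            break
    return pd.DataFrame(rows), selected


def _em_refit(
    v: np.ndarray, W: np.ndarray, max_iter: int = 5000, tol: float = 1e-10
) -> np.ndarray:
    """KL-NMF with fixed signatures: multinomial-EM exposure estimate."""
    K = W.shape[1]
    h = np.full(K, v.sum() / K)
    colsum = np.maximum(W.sum(axis=0), _EPS)
    for _ in range(max_iter):
        R = np.maximum(W @ h, _EPS)
        h_new = h * (W.T @ (v / R)) / colsum
        if np.abs(h_new - h).sum() <= tol * max(1.0, h.sum()):
            h = h_new
            break
        h = h_new
    return h


def fit_exposures(
    spectrum,
    signatures: SignatureMatrix,
    min_fraction: float = 0.05,
    max_iter: int = 5000,
) -> tuple[pd.Series, float]:
    """Fit reference signatures to a spectrum with the 5% prune-and-refit rule.

    All offered signatures are fitted by EM; signatures attributed at most
    ``min_fraction`` of the mutations are dropped and the retained set
    refitted, iterating to a fixed point.  Every candidate set visited is
    scored by the cosine similarity of its reconstruction to the observed
    spectrum, and the best-scoring fit is returned as
    ``(exposures, cosine)`` with exposures indexed by all offered signature
    names (zero for excluded ones).

    An all-zero spectrum returns zero exposures and ``nan`` cosine.
    """
    v = np.asarray(spectrum, dtype=float).ravel()
    W_full = signatures.data.to_numpy(dtype=float)
    names = signatures.names
    if v.shape[0] != W_full.shape[0]:
        raise ValueError(
            f"spectrum has {v.shape[0]} channels but signatures have {W_full.shape[0]}"
        )
    if (v < 0).any():
        raise ValueError("spectrum counts must be non-negative")
    if v.sum() == 0:
        return pd.Series(0.0, index=names), float("nan")

    total = v.sum()
    candidates: list[tuple[tuple[int, ...], np.ndarray, float]] = []
    active = tuple(range(len(names)))
    seen = set()
    while active and active not in seen:
        seen.add(active)
        W = W_full[:, active]
        h = _em_refit(v, W, max_iter=max_iter)
        cos = cosine_similarity(v, W @ h)
        candidates.append((active, h, cos))
        attributed = max(h.sum(), _EPS)
        keep = tuple(i for i, hi in zip(active, h) if hi / attributed > min_fraction)
        if keep == active or not keep:
            break
        active = keep
    best_set, best_h, best_cos = max(candidates, key=lambda c: c[2])
    out = pd.Series(0.0, index=names)
    for i, hi in zip(best_set, best_h):
        out.iloc[i] = hi
    return out, best_cos


def reconstruct_spectrum(signatures: SignatureMatrix, exposures) -> np.ndarray:
    """Linear combination of signatures; total equals the sum of exposures."""
    if isinstance(exposures, pd.Series):
        e = exposures.reindex(signatures.names).to_numpy(dtype=float)
        if np.isnan(e).any():
            raise ValueError("exposure index does not match signature names")
    else:
        e = np.asarray(exposures, dtype=float).ravel()
    if e.shape[0] != signatures.n_signatures:
        raise ValueError(
            f"{e.shape[0]} exposures for {signatures.n_signatures} signatures"
        )
    if (e < 0).any():
        raise ValueError("negative exposure")
    return signatures.data.to_numpy(dtype=float) @ e


def match_reference(
    signature, refdb: SignatureMatrix, confident_threshold: float = 0.85
) -> pd.DataFrame:
    """Rank reference signatures by cosine similarity to a query signature.

    The top match is flagged confident iff its cosine is at or above
    ``confident_threshold`` (inclusive).
    """
    if refdb.n_signatures == 0:
        raise ValueError("empty reference signature set")
    q = np.asarray(signature, dtype=float).ravel()
    rows = []
    for name in refdb.names:
        ref = refdb.column(name)
        try:
            cos = cosine_similarity(q, ref)
        except ValueError:
            cos = 0.0
        rows.append({"reference": name, "cosine": cos})
    out = pd.DataFrame(rows).sort_values("cosine", ascending=False).reset_index(drop=True)
    out["confident"] = False
    # inclusive at the threshold, robust to floating-point rounding
    out.loc[0, "confident"] = bool(out.loc[0, "cosine"] >= confident_threshold - 1e-12)
    return out


def flag_mmr_deficiency(
    exposure_fractions,
    sample_rate: float,
    cohort_rates,
    mmr_signatures=DEFAULT_MMR_SIGNATURES,
    rate_factor: float = 3.0,
    min_mmr_fraction: float = 0.2,
) -> tuple[bool, dict]:
    """Heuristic hypermutator / mismatch-repair-deficiency flag.

    A sample is flagged iff its mutation rate exceeds ``rate_factor`` times
    the cohort median rate AND the summed exposure fraction of the
    MMR-associated signature set is at least ``min_mmr_fraction``.
    ``exposure_fractions`` maps reference-signature names to the fraction of
    the sample's mutations attributed to each (from a reference fit).

    Returns ``(flagged, rationale)`` where the rationale records both clause
    outcomes.
    """
    rates = list(cohort_rates)
    if len(rates) < 3:
        raise ValueError("cohort must have at least 3 samples for a stable median")
    if isinstance(exposure_fractions, pd.Series):
        exposure_fractions = exposure_fractions.to_dict()
    median = float(np.median(rates))
    mmr_fraction = float(
        sum(f for name, f in exposure_fractions.items() if name in set(mmr_signatures))
    )
    rate_elevated = sample_rate > rate_factor * median
    mmr_active = mmr_fraction >= min_mmr_fraction
    rationale = {
        "sample_rate": sample_rate,
        "cohort_median_rate": median,
        "rate_threshold": rate_factor * median,
        "rate_elevated": rate_elevated,
        "mmr_exposure_fraction": mmr_fraction,
        "mmr_fraction_threshold": min_mmr_fraction,
        "mmr_signatures_active": mmr_active,
    }
    return rate_elevated and mmr_active, rationale
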