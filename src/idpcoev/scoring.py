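"""Coupling-score post-processing: APC, scaling, probability calibration,
EC filtering and a mutual-information baseline.

The raw Frobenius coupling norms carry conservation and phylogenetic bias;
the average product correction (APC) subtracts the expected background
S_i*S_j/S from each pair. Corrected scores are then scaled by the mean of
the positive corrected scores, so "1" means an average positive pair and the
reporting threshold (scaled >= 1.30) keeps pairs well above background.
A monotone logistic calibration, fitted class-balanced on synthetic
alignments with known planted pairs, converts scaled scores to a confidence
in [0, 1]; couplings are reported when scaled >= 1.30 AND probability > 0.88.
Both the scaling and the calibration are documented surrogates for the
unpublished normalisations of the original web servers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .alignment import PairedAlignment
from .alphabet import Q

SCORE_MIN = 1.30
PROB_MIN = 0.88
GAP_MASK_FRACTION = 0.5


@dataclass(frozen=True)
class CouplingScore:
    """One scored column pair; i is a column in protein A, j in protein B
    (both 1-based within their own protein)."""

    i: int
    j: int
    raw: float
    apc: float
    scaled: float
    probability: float
    interprotein: bool = True
    gap_masked: bool = False


@dataclass(frozen=True)
class EC(CouplingScore):
    """A reported evolutionary coupling, carrying UniProt numbering and,
    once mapped onto a structure, visibility."""

    idp_uniprot_pos: int = 0
    partner_uniprot_pos: int = 0
    visible: str | None = None  # "visible" | "invisible" | None (undetermined)
    invisible_reason: str | None = None


def apc_correct(S: np.ndarray) -> np.ndarray:
    """Average product correction: S'_ij = S_ij - S_i * S_j / S_mean, with
    row means and the overall mean taken over off-diagonal entries.

    A zero-signal matrix (all off-diagonal mass zero) is returned unchanged.
    """
    S = np.asarray(S, dtype=float)
    L = S.shape[0]
    if L < 2 or not np.allclose(S, S.T, atol=1e-9):
        raise ValueError("APC expects a symmetric matrix of size >= 2")
    off = ~np.eye(L, dtype=bool)
    total_mean = S[off].mean()
    if total_mean == 0:
        return S.copy()
    row_mean = (S.sum(axis=1) - np.diag(S)) / (L - 1)
    corrected = S - np.outer(row_mean, row_mean) / total_mean
    np.fill_diagonal(corrected, 0.0)
    return corrected


def scale_scores(S_corrected: np.ndarray) -> np.ndarray:
    """Divide by the mean positive corrected score, so the positive scores
    average to 1. With no positive score, everything is set to 0 (warned)."""
    S = np.asarray(S_corrected, dtype=float)
    off = ~np.eye(S.shape[0], dtype=bool)
    pos = S[off & (S > 0)]
    if pos.size == 0:
        warnings.warn("no positive corrected scores; scaled scores set to 0")
        return np.zeros_like(S)
    return S / pos.mean()


# ---------------------------------------------------------------------------
# probability calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    """Monotone logistic map from scaled score to coupling probability.

    The curve is a class-balanced one-dimensional logistic regression fitted
    on labelled synthetic scores (planted pairs vs background pairs): the
    returned probability is P(coupled | score) under equal class priors, so
    a score indistinguishable from background maps below 0.5 and the
    reporting cut (probability > 0.88) demands a likelihood ratio of about
    7:1 in favour of a genuine coupling.
    """

    slope: float | None = None
    intercept: float = 0.0

    @property
    def fitted(self) -> bool:
        return self.slope is not None

    def fit(self, scaled_scores: np.ndarray, labels: np.ndarray) -> "CalibrationCurve":
        """Class-balanced 1-D logistic regression on (score, is_planted)."""
        s = np.asarray(scaled_scores, dtype=float)
        y = np.asarray(labels, dtype=float)
        if s.size < 4 or len(np.unique(y)) < 2:
            raise ValueError("calibration needs both planted and background labels")
        n1 = y.sum()
        n0 = len(y) - n1
        w = np.where(y > 0, 0.5 / n1, 0.5 / n0)  # equal class priors

        def nll(params):
            a, b = params
            z = a * s + b
            # the ridge on the slope keeps the curve soft when the classes
            # happen to be linearly separable in the calibration sample
            return float(np.sum(w * (np.logaddexp(0.0, z) - y * z))) + 5e-3 * a * a

        res = minimize(nll, x0=np.array([1.0, -1.0]), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
        a, b = res.x
        if a <= 0:  # enforce monotone non-decreasing mapping
            a = 1e-6
        self.slope = float(a)
        self.intercept = float(b)
        return self

    def __call__(self, scaled_scores: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError(
                "calibration curve is unfitted; run fit() on labelled synthetic "
                "scores (see fit_default_calibration) before converting scores"
            )
        return expit(self.slope * np.asarray(scaled_scores, dtype=float)
                     + self.intercept)


def calibrate_probability(scaled_scores: np.ndarray,
                          calibration: CalibrationCurve) -> np.ndarray:
    """Convert scaled scores to probabilities with a fitted calibration."""
    return calibration(scaled_scores)


def fit_default_calibration(seed: int = 0, n_alignments: int = 3) -> CalibrationCurve:
    """Fit a calibration curve on small synthetic labelled alignments.

    Generates a few paired MSAs with planted pairs across a range of
    strengths, scores them with the Potts engine, and fits the logistic on
    (scaled score, is-planted) labels. Cheap enough to run at pipeline start.
    """
    from .plm import coupling_matrix, fit_mrf
    from .synthetic import SynthConfig, generate_paired_msa
    from .seqprep import sequence_weights

    scores_all, labels_all = [], []
    rng = np.random.default_rng(seed)
    for k in range(n_alignments):
        # spread strengths from near-background to strong so the logistic
        # sees borderline cases, not only saturated ones
        cfg = SynthConfig(
            n_species=300, len_idp=20, len_partner=20,
            planted_pairs=((3, 5, 0.25), (8, 11, 0.4), (12, 2, 0.6),
                           (16, 18, 0.8)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        aln, truth = generate_paired_msa(cfg)
        aln.weights = sequence_weights(aln)
        model = fit_mrf(aln, max_iter=150)
        S = scale_scores(apc_correct(coupling_matrix(model)))
        planted = {(i, j) for i, j in truth.pairs}
        for i in range(1, cfg.len_idp + 1):
            for j in range(1, cfg.len_partner + 1):
                scores_all.append(S[i - 1, cfg.len_idp + j - 1])
                labels_all.append(1.0 if (i, j) in planted else 0.0)
    return CalibrationCurve().fit(np.array(scores_all), np.array(labels_all))


# ---------------------------------------------------------------------------
# EC extraction
# ---------------------------------------------------------------------------


def interprotein_pairs(L: int, boundary: int) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (i, j) of all interprotein column pairs, i <= boundary < j
    in 1-based terms (0-based: i < boundary <= j)."""
    ii, jj = np.meshgrid(np.arange(boundary), np.arange(boundary, L), indexing="ij")
    return ii.ravel(), jj.ravel()


def score_couplings(
    aln: PairedAlignment,
    model,
    calibration: CalibrationCurve,
) -> list[CouplingScore]:
    """Score every interprotein column pair of a fitted model.

    Columns with more than 50% gaps are masked: pairs touching them are kept
    in the table but flagged ``gap_masked`` and excluded from EC reporting
    (gappy disordered columns are the engine's known failure mode).
    """
    from .plm import coupling_matrix

    S_raw = coupling_matrix(model)
    S_apc = apc_correct(S_raw)
    S_scaled = scale_scores(S_apc)
    b = aln.boundary
    ii, jj = interprotein_pairs(aln.n_cols, b)
    run_scores = S_scaled[ii, jj]
    probs = calibrate_probability(run_scores, calibration)
    gappy = aln.gap_fraction() > GAP_MASK_FRACTION
    out = []
    for k, (i0, j0) in enumerate(zip(ii, jj)):
        out.append(CouplingScore(
            i=int(i0) + 1,
            j=int(j0) - b + 1,
            raw=float(S_raw[i0, j0]),
            apc=float(S_apc[i0, j0]),
            scaled=float(S_scaled[i0, j0]),
            probability=float(probs[k]),
            interprotein=True,
            gap_masked=bool(gappy[i0] or gappy[j0]),
        ))
    return out


def filter_ecs(
    scores: list[CouplingScore],
    boundary: int,
    idp_region=None,
    partner_region=None,
    score_min: float = SCORE_MIN,
    prob_min: float = PROB_MIN,
) -> list[EC]:
    """Keep interprotein pairs with scaled >= score_min and probability >
    prob_min (thresholds inclusive/exclusive exactly as stated), mapping
    protein-local columns to UniProt numbering via the trimmed regions."""
    ecs = []
    for cs in scores:
        if not cs.interprotein or cs.gap_masked:
            continue
        if cs.scaled < score_min or cs.probability <= prob_min:
            continue
        idp_pos = idp_region.to_uniprot(cs.i) if idp_region is not None else cs.i
        partner_pos = (partner_region.to_uniprot(cs.j)
                       if partner_region is not None else cs.j)
        ecs.append(EC(
            i=cs.i, j=cs.j, raw=cs.raw, apc=cs.apc, scaled=cs.scaled,
            probability=cs.probability, interprotein=True,
            gap_masked=cs.gap_masked,
            idp_uniprot_pos=idp_pos, partner_uniprot_pos=partner_pos,
        ))
    return ecs


def write_ec_table(path, scores: list[CouplingScore], ecs: list[EC]) -> None:
    """TSV dump of all interprotein pairs; reported ECs carry UniProt numbers."""
    reported = {(ec.i, ec.j): ec for ec in ecs}
    with open(path, "w") as fh:
        fh.write("idp_col\tpartner_col\tidp_uniprot\tpartner_uniprot\traw\tapc\t"
                 "scaled\tprobability\tinterprotein\treported\n")
        for cs in scores:
            ec = reported.get((cs.i, cs.j))
            iu = ec.idp_uniprot_pos if ec else ""
            ju = ec.partner_uniprot_pos if ec else ""
            fh.write(f"{cs.i}\t{cs.j}\t{iu}\t{ju}\t{cs.raw:.6g}\t{cs.apc:.6g}\t"
                     f"{cs.scaled:.6g}\t{cs.probability:.6g}\t"
                     f"{int(cs.interprotein)}\t{int(ec is not None)}\n")


# ---------------------------------------------------------------------------
# mutual-information baseline
# ---------------------------------------------------------------------------


def mi_baseline(aln: PairedAlignment, apc: bool = True) -> np.ndarray:
    """Weighted plug-in mutual information (bits) per column pair, optionally
    APC-corrected. Serves as an independent ranking baseline for the Potts
    scores; it does not remove transitive correlations."""
    X = aln.matrix.astype(np.int64)
    N, L = X.shape
    w = aln.weights if aln.weights is not None else np.ones(N)
    wn = w / w.sum()
    Xoh = np.zeros((N, L * Q))
    Xoh[np.arange(N)[:, None], np.arange(L) * Q + X] = 1.0
    joint = (Xoh * wn[:, None]).T @ Xoh  # (L*Q, L*Q) joint frequencies
    joint = joint.reshape(L, Q, L, Q)
    marg = np.einsum("n,nlq->lq", wn, Xoh.reshape(N, L, Q))
    mi = np.zeros((L, L))
    for i in range(L):
        pij = joint[i, :, :, :]  # (Q, L, Q)
        indep = marg[i][:, None, None] * marg[None, :, :]  # (Q, L, Q)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = pij * (np.log2(pij) - np.log2(indep))
        mi[i] = np.nansum(term, axis=(0, 2))
    np.fill_diagonal(mi, 0.0)
    mi = 0.5 * (mi + mi.T)  # symmetrise away accumulation noise
    mi = np.maximum(mi, 0.0)
    return apc_correct(mi) if apc else mi


def column_mi(aln: PairedAlignment, col_a: int, col_b: int) -> float:
    """Unweighted plug-in MI (bits) between two 0-based columns."""
    x = aln.matrix[:, col_a].astype(int)
    y = aln.matrix[:, col_b].astype(int)
    joint = np.zeros((Q, Q))
    np.add.at(joint, (x, y), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])).sum())
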