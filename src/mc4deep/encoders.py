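"""The eight preliminary sequence-feature encodings.

Each scheme maps a fixed-length DNA window to a numeric feature vector:

==========  ====================================================  ======
scheme      content                                               length
==========  ====================================================  ======
BKF         per-position one-hot + k-mer frequencies (k=2,3,4)    500
DBPF        dinucleotide one-hot + running dinucleotide freq      680
KNN         positive fraction among nearest labelled neighbours   10
PCP         six physicochemical dinucleotide scales per position  240
MMI         pairwise + three-way mutual information of content    30
PseDNC      pseudo dinucleotide composition (lambda tiers)        19
PseEIIP     EIIP-weighted trinucleotide frequencies               64
RFHCP       ring/H-bond/functional-group bits + cumulative freq   164
==========  ====================================================  ======

Lengths are for the default 41-bp window.  The published description
names the schemes but defers every numeric detail to its references, so
the exact formulations here (k ranges, lambda, weight, property table,
neighbourhood fractions) are pinned package constants, documented in
``docs/methods.md`` and overridable through :class:`EncoderParams`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .folds import FoldAssignment
from .samples import DnaSample

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class Scheme(str, Enum):
    """The eight encodings, in the fixed column order used everywhere."""

    BKF = "bkf"
    DBPF = "dbpf"
    KNN = "knn"
    PCP = "pcp"
    MMI = "mmi"
    PSEDNC = "psednc"
    PSEEIIP = "pseeiip"
    RFHCP = "rfhcp"

    @classmethod
    def from_name(cls, name: str) -> "Scheme":
        try:
            return cls(name.lower())
        except ValueError:
            raise ValueError(f"unknown encoding scheme {name!r}") from None


SCHEME_ORDER: tuple[Scheme, ...] = tuple(Scheme)

# Electron-ion interaction pseudopotential of each nucleotide.
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}

# Chemical-property bits: ring structure (purine=1), hydrogen-bond
# strength (strong/G,C=1), functional group (amino/A,C=1).
CHEMICAL_BITS = {
    "A": (1, 0, 1),
    "C": (0, 1, 1),
    "G": (1, 1, 0),
    "T": (0, 0, 0),
}

# Six B-DNA dinucleotide step-parameter scales (twist, tilt, roll in
# degrees; shift, slide, rise in angstrom).  Reverse-complement
# symmetric, physically plausible magnitudes; each scale is standardized
# (zero mean, unit variance over the 16 dinucleotides) before use, so
# only the relative differences between dinucleotides enter the PCP and
# PseDNC coordinates.  The table is a pinned package constant.
_STEP_PARAMS_10 = {
    #        twist  tilt  roll  shift  slide  rise
    "AA": (35.1, 0.5, 0.3, 0.01, -0.08, 3.27),
    "AC": (31.5, 0.1, 0.5, 0.13, -0.58, 3.36),
    "AG": (31.9, 2.8, 4.5, 0.02, -0.25, 3.34),
    "AT": (29.3, 0.0, -0.8, 0.00, -0.59, 3.31),
    "CA": (37.3, 0.5, 4.7, 0.16, 0.53, 3.33),
    "CC": (32.9, 0.7, 3.6, 0.02, -0.22, 3.42),
    "CG": (36.1, 0.0, 5.4, 0.00, 0.41, 3.39),
    "GA": (36.3, 1.3, 1.9, 0.27, 0.09, 3.37),
    "GC": (33.6, 0.0, 0.3, 0.00, -0.38, 3.40),
    "TA": (37.8, 0.0, 3.3, 0.00, 0.05, 3.42),
}
_COMPLEMENT = str.maketrans(BASES, "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _build_step_table() -> dict[str, np.ndarray]:
    raw = {}
    for d in map("".join, itertools.product(BASES, repeat=2)):
        src = d if d in _STEP_PARAMS_10 else _revcomp(d)
        raw[d] = np.asarray(_STEP_PARAMS_10[src], dtype=float)
    mat = np.stack([raw[d] for d in sorted(raw)])
    mean, std = mat.mean(axis=0), mat.std(axis=0)
    return {d: (v - mean) / std for d, v in raw.items()}


STEP_PARAMS: dict[str, np.ndarray] = _build_step_table()
N_STEP_SCALES = 6

DINUCS = tuple(map("".join, itertools.product(BASES, repeat=2)))
TRINUCS = tuple(map("".join, itertools.product(BASES, repeat=3)))
_DINUC_INDEX = {d: i for i, d in enumerate(DINUCS)}
_TRINUC_INDEX = {t: i for i, t in enumerate(TRINUCS)}

# Unordered nucleotide pairs / triples (multisets), lexicographic.
PAIRS = tuple("".join(p) for p in itertools.combinations_with_replacement(BASES, 2))
TRIPLES = tuple("".join(t) for t in itertools.combinations_with_replacement(BASES, 3))


@dataclass(frozen=True)
class EncoderParams:
    """Tunable constants shared by the encoders."""

    kmer_ks: tuple[int, ...] = (2, 3, 4)
    pse_lambda: int = 3
    pse_weight: float = 0.1
    knn_fractions: tuple[float, ...] = tuple(round(0.02 * i, 2) for i in range(1, 11))

    def __post_init__(self):
        if self.pse_lambda < 1:
            raise ValueError("pse_lambda must be >= 1")
        if not 0 <= self.pse_weight:
            raise ValueError("pse_weight must be non-negative")
        if not self.knn_fractions or any(not 0 < f <= 1 for f in self.knn_fractions):
            raise ValueError("knn_fractions must be in (0, 1]")


DEFAULT_PARAMS = EncoderParams()


def feature_length(
    scheme: Scheme | str, L: int = 41, params: EncoderParams = DEFAULT_PARAMS
) -> int:
    """Closed-form feature-vector length of a scheme for window length L."""
    scheme = Scheme.from_name(scheme) if isinstance(scheme, str) else scheme
    if scheme is Scheme.BKF:
        return 4 * L + sum(4**k for k in params.kmer_ks)
    if scheme is Scheme.DBPF:
        return (L - 1) * 17
    if scheme is Scheme.KNN:
        return len(params.knn_fractions)
    if scheme is Scheme.PCP:
        return (L - 1) * N_STEP_SCALES
    if scheme is Scheme.MMI:
        return len(PAIRS) + len(TRIPLES)
    if scheme is Scheme.PSEDNC:
        return 16 + params.pse_lambda
    if scheme is Scheme.PSEEIIP:
        return 64
    if scheme is Scheme.RFHCP:
        return 4 * L
    raise ValueError(f"unknown scheme {scheme!r}")


def feature_names(
    scheme: Scheme | str, L: int = 41, params: EncoderParams = DEFAULT_PARAMS
) -> list[str]:
    """Column names matching :func:`encode` output order."""
    scheme = Scheme.from_name(scheme) if isinstance(scheme, str) else scheme
    if scheme is Scheme.BKF:
        names = [f"onehot_p{i + 1}_{b}" for i in range(L) for b in BASES]
        for k in params.kmer_ks:
            names += [f"freq_{''.join(m)}" for m in itertools.product(BASES, repeat=k)]
        return names
    if scheme is Scheme.DBPF:
        return [
            f"p{j + 1}_{col}"
            for j in range(L - 1)
            for col in [f"is_{d}" for d in DINUCS] + ["runfreq"]
        ]
    if scheme is Scheme.KNN:
        return [f"posfrac_top{f:g}" for f in params.knn_fractions]
    if scheme is Scheme.PCP:
        scales = ("twist", "tilt", "roll", "shift", "slide", "rise")
        return [f"p{j + 1}_{s}" for j in range(L - 1) for s in scales]
    if scheme is Scheme.MMI:
        return [f"I2_{p}" for p in PAIRS] + [f"I3_{t}" for t in TRIPLES]
    if scheme is Scheme.PSEDNC:
        return [f"d_{d}" for d in DINUCS] + [
            f"theta_{j + 1}" for j in range(params.pse_lambda)
        ]
    if scheme is Scheme.PSEEIIP:
        return [f"eiip_{t}" for t in TRINUCS]
    if scheme is Scheme.RFHCP:
        return [
            f"p{i + 1}_{c}"
            for i in range(L)
            for c in ("ring", "hbond", "func", "cumfreq")
        ]
    raise ValueError(f"unknown scheme {scheme!r}")


def _seq_of(sample: DnaSample | str) -> str:
    return sample.sequence if isinstance(sample, DnaSample) else sample


def _as_indices(seq: str) -> np.ndarray:
    return np.asarray([_BASE_INDEX[b] for b in seq], dtype=np.int64)


def _kmer_freqs(seq: str, k: int) -> np.ndarray:
    counts = np.zeros(4**k)
    for i in range(len(seq) - k + 1):
        idx = 0
        for b in seq[i : i + k]:
            idx = idx * 4 + _BASE_INDEX[b]
        counts[idx] += 1
    return counts / (len(seq) - k + 1)


def _encode_bkf(seq: str, params: EncoderParams) -> np.ndarray:
    onehot = np.zeros((len(seq), 4))
    onehot[np.arange(len(seq)), _as_indices(seq)] = 1.0
    blocks = [onehot.ravel()]
    blocks += [_kmer_freqs(seq, k) for k in params.kmer_ks]
    return np.concatenate(blocks)


def _encode_dbpf(seq: str, params: EncoderParams) -> np.ndarray:
    L = len(seq)
    out = np.zeros((L - 1, 17))
    running = np.zeros(16)
    for j in range(L - 1):
        d = _DINUC_INDEX[seq[j : j + 2]]
        out[j, d] = 1.0
        running[d] += 1
        out[j, 16] = running[d] / (j + 1)
    return out.ravel()


def _encode_pcp(seq: str, params: EncoderParams) -> np.ndarray:
    rows = [STEP_PARAMS[seq[j : j + 2]] for j in range(len(seq) - 1)]
    return np.concatenate(rows)


def _multiset_freqs(seq: str, k: int, keys: tuple[str, ...]) -> dict[str, float]:
    counts = dict.fromkeys(keys, 0)
    n = len(seq) - k + 1
    for i in range(n):
        counts["".join(sorted(seq[i : i + k]))] += 1
    return {key: c / n for key, c in counts.items()}


def _encode_mmi(seq: str, params: EncoderParams) -> np.ndarray:
    """Pairwise and interaction mutual information of window composition.

    I2(x,y) = f(xy) ln(f(xy) / (f(x) f(y))) over unordered 2-mer content;
    I3(x,y,z) = I2(x,y) - f(xyz) ln(f(z) f(xyz) / (f(xz) f(yz))).
    Any term touching a zero frequency is defined as 0.
    """
    f1 = {b: seq.count(b) / len(seq) for b in BASES}
    f2 = _multiset_freqs(seq, 2, PAIRS)
    f3 = _multiset_freqs(seq, 3, TRIPLES)

    def pair_f(x: str, y: str) -> float:
        return f2["".join(sorted(x + y))]

    def i2(x: str, y: str) -> float:
        fxy = pair_f(x, y)
        if fxy == 0 or f1[x] == 0 or f1[y] == 0:
            return 0.0
        return fxy * math.log(fxy / (f1[x] * f1[y]))

    out = [i2(p[0], p[1]) for p in PAIRS]
    for t in TRIPLES:
        x, y, z = t
        fxyz = f3[t]
        fxz, fyz = pair_f(x, z), pair_f(y, z)
        if fxyz == 0 or f1[z] == 0 or fxz == 0 or fyz == 0:
            cond = 0.0
        else:
            cond = fxyz * math.log(f1[z] * fxyz / (fxz * fyz))
        out.append(i2(x, y) - cond)
    return np.asarray(out)


def _encode_psednc(seq: str, params: EncoderParams) -> np.ndarray:
    L = len(seq)
    lam, w = params.pse_lambda, params.pse_weight
    if lam > L - 2:
        raise ValueError(f"pse_lambda {lam} too large for window length {L}")
    freqs = np.zeros(16)
    for j in range(L - 1):
        freqs[_DINUC_INDEX[seq[j : j + 2]]] += 1
    freqs /= L - 1

    # Correlation tiers: mean squared difference of the six standardized
    # step scales between dinucleotides j positions apart.
    steps = np.stack([STEP_PARAMS[seq[j : j + 2]] for j in range(L - 1)])
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diffs = steps[:-j] - steps[j:]
        thetas[j - 1] = np.mean(np.sum(diffs**2, axis=1) / N_STEP_SCALES)
    denom = 1.0 + w * thetas.sum()
    return np.concatenate([freqs / denom, w * thetas / denom])


def _encode_pseeiip(seq: str, params: EncoderParams) -> np.ndarray:
    freqs = np.zeros(64)
    for i in range(len(seq) - 2):
        freqs[_TRINUC_INDEX[seq[i : i + 3]]] += 1
    freqs /= len(seq) - 2
    weights = np.asarray([sum(EIIP[b] for b in t) for t in TRINUCS])
    return weights * freqs


def _encode_rfhcp(seq: str, params: EncoderParams) -> np.ndarray:
    L = len(seq)
    out = np.zeros((L, 4))
    counts = dict.fromkeys(BASES, 0)
    for i, b in enumerate(seq):
        counts[b] += 1
        out[i, :3] = CHEMICAL_BITS[b]
        out[i, 3] = counts[b] / (i + 1)
    return out.ravel()


_PURE_ENCODERS = {
    Scheme.BKF: _encode_bkf,
    Scheme.DBPF: _encode_dbpf,
    Scheme.PCP: _encode_pcp,
    Scheme.MMI: _encode_mmi,
    Scheme.PSEDNC: _encode_psednc,
    Scheme.PSEEIIP: _encode_pseeiip,
    Scheme.RFHCP: _encode_rfhcp,
}


def encode(
    sample: DnaSample | str,
    scheme: Scheme | str,
    params: EncoderParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Encode one window under a reference-free scheme (not KNN)."""
    scheme = Scheme.from_name(scheme) if isinstance(scheme, str) else scheme
    if scheme is Scheme.KNN:
        raise ValueError("KNN needs a labelled reference set; use encode_knn")
    seq = _seq_of(sample)
    largest_k = {
        Scheme.BKF: max(params.kmer_ks),
        Scheme.DBPF: 2,
        Scheme.PCP: 2,
        Scheme.MMI: 3,
        Scheme.PSEDNC: 2,
        Scheme.PSEEIIP: 3,
        Scheme.RFHCP: 1,
    }[scheme]
    if len(seq) < largest_k:
        raise ValueError(
            f"sequence length {len(seq)} shorter than scheme {scheme.value} k={largest_k}"
        )
    vec = _PURE_ENCODERS[scheme](seq, params)
    assert len(vec) == feature_length(scheme, len(seq), params)
    return vec


def knn_similarity(query: str, references: np.ndarray) -> np.ndarray:
    """Per-position identity similarity (matches / L) to each reference row."""
    q = _as_indices(query)
    return (references == q).mean(axis=1)


def _knn_from_sims(sims: np.ndarray, ref_labels: np.ndarray,
                   fractions: Sequence[float]) -> np.ndarray:
    """KNN feature rows from a (n_queries, n_refs) similarity matrix.

    Ties in similarity are broken by reference input order (stable sort).
    """
    n_refs = sims.shape[1]
    order = np.argsort(-sims, axis=1, kind="stable")
    sorted_labels = np.take_along_axis(
        np.broadcast_to(ref_labels, sims.shape), order, axis=1
    )
    cum = np.cumsum(sorted_labels, axis=1)
    sizes = np.asarray([math.ceil(f * n_refs) for f in fractions])
    return cum[:, sizes - 1] / sizes


def encode_knn(
    sample: DnaSample | str,
    reference_samples: Sequence[DnaSample],
    params: EncoderParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Positive-label fraction among the nearest labelled references.

    For each fraction f, takes the ceil(f * n_refs) nearest references
    under per-position identity similarity (ties broken by reference
    input order) and reports the proportion of positives among them.
    """
    return encode_knn_batch([sample], reference_samples, params)[0]


def encode_knn_batch(
    samples: Sequence[DnaSample | str],
    reference_samples: Sequence[DnaSample],
    params: EncoderParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Vectorized :func:`encode_knn` over many query windows."""
    if not reference_samples:
        raise ValueError("empty KNN reference set")
    q_mat = np.stack([_as_indices(_seq_of(s)) for s in samples])
    ref_mat = np.stack([_as_indices(r.sequence) for r in reference_samples])
    ref_labels = np.asarray([r.label for r in reference_samples], dtype=float)
    sims = (q_mat[:, None, :] == ref_mat[None, :, :]).mean(axis=2)
    return _knn_from_sims(sims, ref_labels, params.knn_fractions)


@dataclass
class EncodedMatrix:
    """One encoding scheme applied to an ordered dataset."""

    scheme: Scheme
    ids: tuple[str, ...]
    matrix: np.ndarray  # (n, feature_length)
    params: EncoderParams = field(default_factory=EncoderParams)

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix rows must match sample ids")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def encode_dataset(
    samples: Sequence[DnaSample],
    scheme: Scheme | str,
    folds: FoldAssignment | None = None,
    params: EncoderParams = DEFAULT_PARAMS,
    L: int = 41,
) -> EncodedMatrix:
    """Encode a whole dataset; KNN rows are computed out-of-fold.

    For the KNN scheme a :class:`FoldAssignment` is required and each
    row's references are restricted to samples in *other* folds, so the
    label-derived feature never sees its own fold.
    """
    scheme = Scheme.from_name(scheme) if isinstance(scheme, str) else scheme
    ids = tuple(s.id for s in samples)
    width = feature_length(scheme, L if not samples else len(samples[0].sequence), params)
    if not samples:
        return EncodedMatrix(scheme, ids, np.empty((0, width)), params)
    if scheme is Scheme.KNN:
        if folds is None:
            raise ValueError("KNN encoding requires a fold assignment (leakage guard)")
        idx_mat = np.stack([_as_indices(s.sequence) for s in samples])
        all_labels = np.asarray([s.label for s in samples], dtype=float)
        rows = np.empty((len(samples), width))
        for fold in range(folds.k):
            q = folds.rows_in_fold(fold)
            r = folds.rows_not_in_fold(fold)
            sims = (idx_mat[q][:, None, :] == idx_mat[r][None, :, :]).mean(axis=2)
            rows[q] = _knn_from_sims(sims, all_labels[r], params.knn_fractions)
        return EncodedMatrix(scheme, ids, rows, params)
    mat = np.stack([encode(s, scheme, params) for s in samples])
    return EncodedMatrix(scheme, ids, mat, params)


def write_matrix_tsv(
    encoded: EncodedMatrix, tsv_path, sidecar_path=None, L: int = 41
) -> None:
    """Export as TSV (``id`` + feature-name header) with a JSON sidecar."""
    import json
    from pathlib import Path

    names = feature_names(encoded.scheme, L, encoded.params)
    if len(names) != encoded.n_features:  # e.g. non-default window length
        names = [f"f{i}" for i in range(encoded.n_features)]
    with open(tsv_path, "w") as fh:
        fh.write("id\t" + "\t".join(names) + "\n")
        for sid, row in zip(encoded.ids, encoded.matrix):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    if sidecar_path is not None:
        meta = {
            "scheme": encoded.scheme.value,
            "n_samples": len(encoded.ids),
            "n_features": encoded.n_features,
            "params": {
                "kmer_ks": list(encoded.params.kmer_ks),
                "pse_lambda": encoded.params.pse_lambda,
                "pse_weight": encoded.params.pse_weight,
                "knn_fractions": list(encoded.params.knn_fractions),
            },
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")
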