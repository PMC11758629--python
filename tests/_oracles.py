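"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import numpy as np

from strdose.scan import ScanThresholds


def primitive(unit: str) -> bool:
    p = len(unit)
    return not any(p % d == 0 and unit == unit[:d] * (p // d) for d in range(1, p))


def brute_force_scan(seq: str, thresholds: ScanThresholds) -> set[tuple]:
    """Enumerate every maximal run of every primitive unit of period 1-6.

    A candidate run starts at i with unit seq[i:i+p]; it is the canonical
    representative of its maximal region iff position i-1 does not also
    repeat at lag p (base-level left-maximality).  Returns tuples of
    (start_1based, end_1based, motif, period, n_repeats).
    """
    seq = seq.upper()
    n = len(seq)
    out = set()
    for p, min_rep in thresholds.min_repeats_by_period.items():
        for i in range(n - 2 * p + 1):
            unit = seq[i : i + p]
            if any(c not in "ACGT" for c in unit) or not primitive(unit):
                continue
            if i > 0 and seq[i - 1] == seq[i + p - 1]:
                continue
            k = 1
            while seq[i + k * p : i + (k + 1) * p] == unit:
                k += 1
            if k >= min_rep and k * p >= thresholds.min_region_bp:
                out.add((i + 1, i + k * p, unit, p, k))
    return out


def str_rich_sequence(rng: np.random.Generator, length: int) -> str:
    """AT-biased random sequence with several planted repeat runs."""
    s = list(rng.choice(list("ACGT"), p=[0.35, 0.15, 0.15, 0.35], size=length))
    for _ in range(int(rng.integers(3, 9))):
        p = int(rng.integers(1, 7))
        unit = "".join(rng.choice(list("ACGT"), size=p))
        k = int(rng.integers(3, 16))
        if p * k >= length:
            continue
        pos = int(rng.integers(0, length - p * k))
        s[pos : pos + p * k] = list(unit * k)
    return "".join(s)


def recursive_kinship(ped_records) -> np.ndarray:
    """Pedigree kinship by the classic recursion; A = 2 * kinship.

    ``ped_records`` is a DataFrame with columns id, sire, dam in
    parents-first order (None for unknown parents).
    """
    ids = list(ped_records["id"])
    pos = {v: i for i, v in enumerate(ids)}
    parents = {
        pos[r.id]: (
            pos[r.sire] if r.sire is not None else None,
            pos[r.dam] if r.dam is not None else None,
        )
        for r in ped_records.itertuples()
    }
    cache: dict[tuple[int, int], float] = {}

    def f(i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        if (i, j) in cache:
            return cache[(i, j)]
        if i == j:
            s, d = parents[i]
            val = 0.5 * (1.0 + (f(s, d) if s is not None and d is not None else 0.0))
        else:
            # j is the later individual: recurse through j's parents
            s, d = parents[j]
            val = 0.5 * (
                (f(i, s) if s is not None else 0.0)
                + (f(i, d) if d is not None else 0.0)
            )
        cache[(i, j)] = val
        return val

    n = len(ids)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = f(i, j)
    return 2.0 * K


def dense_reml_loglik(y, X, G, sigma_a2, sigma_e2):
    """REML log-likelihood from the dense V-matrix formula (Harville form,
    without the constant ln|X'X| term)."""
    n, q = X.shape
    V = sigma_a2 * G + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    b = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ b
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - q) * np.log(2 * np.pi) + ld_v + ld_x + r @ Vi @ r)


def blup_gls_oracle(y, X, Z, A, sigma_a2, sigma_e2):
    """Mixed-model solutions via the GLS identities rather than the MME."""
    V = sigma_a2 * (Z @ A @ Z.T) + sigma_e2 * np.eye(len(y))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    b = np.linalg.solve(XtViX, X.T @ Vi @ y)
    a = sigma_a2 * A @ Z.T @ Vi @ (y - X @ b)
    return b, a
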