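import numpy as np
import pytest

from bridgescan.seqio import SeqRecord
from bridgescan.simulate import FamilyTruth, gen_orthologue_family


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_family():
    """One coupled orthologue family shared by covariation tests."""
    truth = FamilyTruth.random(11, n_orthologues=120, coupling=0.9,
                               sub_rate=0.2)
    bridge, target, donor = gen_orthologue_family(truth)
    return truth, bridge, target, donor


@pytest.fixture
def genome_record(rng):
    return SeqRecord("g", random_dna(rng, 5000))


# ---------------------------------------------------------------------------
# independent oracles


def smith_waterman(q: str, s: str, match=1, mismatch=-1, gap=-2):
    """Full O(mn) local alignment; returns (score, q0, q1, s0, s1)."""
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = match if q[i - 1] == s[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + sub, H[i - 1, j] + gap,
                          H[i, j - 1] + gap)
    score = int(H.max())
    i, j = map(int, np.unravel_index(H.argmax(), H.shape))
    q1, s1 = i, j
    while H[i, j] > 0:
        sub = match if q[i - 1] == s[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + sub:
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return score, i, q1, j, s1


def levenshtein_dp(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def concordance_bruteforce(bridge_rows, partner_rows):
    """Double-loop oracle for the per-column-pair concordance score."""
    Lb, Lt = len(bridge_rows[0]), len(partner_rows[0])
    C = np.full((Lb, Lt), np.nan)
    for i in range(Lb):
        for j in range(Lt):
            match = comp = n = 0
            for s, t in zip(bridge_rows, partner_rows):
                a, b = s[i], t[j]
                if a not in "ACGT" or b not in "ACGT":
                    continue
                n += 1
                if a == b:
                    match += 1
                if _COMP[a] == b:
                    comp -= 1
            if n:
                C[i, j] = (match if match >= -comp else comp) / n
    return C
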