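"""Best-match search of query chains against a repertoire.

Semantics are exhaustive: ``best_match`` must return exactly what a plain
scan over every eligible template would (``exhaustive_best_match`` is that
scan, kept as an independent oracle).  The index only accelerates:

* full-chain mode — a dense residue-code matrix over the chain partition's
  position vocabulary, scanned with vectorised equality counts;
* CDR-triplet mode — buckets keyed by the (len1, len2, len3) loop-length
  signature, which the comparability rule already requires to match;
* CDR-H3 mode — a loop-length bucket plus an exact-string hash map that
  resolves perfect matches in O(1).

Ties on the best value are broken to the earliest record in repertoire
insertion order; ``tie_count`` preserves how many templates achieved the
best value.  Tie comparisons use exact rational arithmetic, never floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .identity import (
    IdentityScore,
    Mode,
    cdr_triplet_identity,
    cdrh3_identity,
    positional_identity,
)
from .imgt import IMGT_SCHEME, ImgtPosition, RegionScheme, extract_cdrs
from .io import Chain, NumberedChain, StudyMetadata


@dataclass(frozen=True)
class MatchResult:
    """Best-identity outcome of one query against a repertoire in one mode."""

    query_id: str
    mode: Mode
    best_value: float
    best_template_id: str
    tie_count: int
    source: Optional[StudyMetadata]
    matches: int
    len_query: int
    len_template: int

    @property
    def score(self) -> IdentityScore:
        return IdentityScore.from_counts(
            self.matches, self.len_query, self.len_template, self.mode
        )

    @property
    def exact(self) -> Fraction:
        return self.score.exact


@dataclass
class _Entry:
    order: int
    chain: NumberedChain
    cdrs: tuple[str, str, str]


class RepertoireIndex:
    """In-memory search index over a repertoire of numbered chains."""

    def __init__(self, scheme: RegionScheme = IMGT_SCHEME):
        self.scheme = scheme
        self.by_chain: dict[Chain, list[_Entry]] = {Chain.HEAVY: [], Chain.LIGHT: []}
        self.by_cdr_lengths: dict[tuple[Chain, tuple[int, int, int]], list[_Entry]] = {}
        self.by_cdrh3_length: dict[tuple[Chain, int], list[_Entry]] = {}
        self.cdrh3_exact: dict[tuple[Chain, str], list[_Entry]] = {}
        self._n = 0
        self._matrix_cache: dict[Chain, tuple] = {}

    def __len__(self) -> int:
        return self._n

    def add(self, record: NumberedChain) -> None:
        cdrs = extract_cdrs(record, self.scheme)
        entry = _Entry(order=self._n, chain=record, cdrs=cdrs)
        self._n += 1
        self.by_chain[record.chain].append(entry)
        lengths = tuple(len(c) for c in cdrs)
        self.by_cdr_lengths.setdefault((record.chain, lengths), []).append(entry)
        if cdrs[2]:
            self.by_cdrh3_length.setdefault((record.chain, len(cdrs[2])), []).append(entry)
            self.cdrh3_exact.setdefault((record.chain, cdrs[2]), []).append(entry)
        self._matrix_cache.pop(record.chain, None)

    # -- dense full-chain representation ------------------------------------

    def _chain_matrix(self, chain: Chain):
        """(entries, vocab index, uint8 code matrix, template lengths)."""
        cached = self._matrix_cache.get(chain)
        if cached is not None:
            return cached
        entries = self.by_chain[chain]
        vocab: dict[ImgtPosition, int] = {}
        for e in entries:
            for pos in e.chain.residues:
                if pos not in vocab:
                    vocab[pos] = len(vocab)
        mat = np.zeros((len(entries), len(vocab)), dtype=np.uint8)
        lens = np.empty(len(entries), dtype=np.int64)
        for i, e in enumerate(entries):
            lens[i] = len(e.chain)
            for pos, aa in e.chain.residues.items():
                # 'X' never matches; give it a code no query code can equal
                mat[i, vocab[pos]] = 254 if aa == "X" else ord(aa)
        cached = (entries, vocab, mat, lens)
        self._matrix_cache[chain] = cached
        return cached


def build_index(
    repertoire: Iterable[NumberedChain], scheme: RegionScheme = IMGT_SCHEME
) -> RepertoireIndex:
    """Single-pass index construction; insertion order follows the stream."""
    index = RepertoireIndex(scheme)
    for record in repertoire:
        index.add(record)
    return index


def _pick_best_equal_length(
    query: NumberedChain, mode: Mode, candidates: Sequence[_Entry], match_counts
) -> Optional[MatchResult]:
    """Best over candidates whose identity is m/L with one shared L."""
    if not candidates:
        return None
    best_m = -1
    best_entry = None
    ties = 0
    for entry, m in zip(candidates, match_counts):
        if m > best_m:
            best_m, best_entry, ties = m, entry, 1
        elif m == best_m:
            ties += 1
            if entry.order < best_entry.order:
                best_entry = entry
    L = _mode_length(query, mode, best_entry)
    return MatchResult(
        query_id=query.record_id,
        mode=mode,
        best_value=best_m / L,
        best_template_id=best_entry.chain.record_id,
        tie_count=ties,
        source=best_entry.chain.meta,
        matches=best_m,
        len_query=L,
        len_template=L,
    )


def _mode_length(query: NumberedChain, mode: Mode, entry: _Entry) -> int:
    if mode is Mode.CDR_TRIPLET:
        return sum(len(c) for c in entry.cdrs)
    return len(entry.cdrs[2])


def _string_matches(q: str, t: str) -> int:
    return sum(1 for a, b in zip(q, t) if a == b and a != "X")


def best_match(
    query: NumberedChain, index: RepertoireIndex, mode: Mode
) -> Optional[MatchResult]:
    """Best-identity template for one query, or None when nothing is eligible.

    Equivalent to :func:`exhaustive_best_match` over the indexed records.
    """
    qcdrs = extract_cdrs(query, index.scheme)

    if mode is Mode.FULL_CHAIN:
        return _best_full_chain(query, index)

    if mode is Mode.CDR_TRIPLET:
        if not "".join(qcdrs):
            return None
        lengths = tuple(len(c) for c in qcdrs)
        bucket = index.by_cdr_lengths.get((query.chain, lengths), [])
        qcat = "".join(qcdrs)
        counts = [_string_matches(qcat, "".join(e.cdrs)) for e in bucket]
        return _pick_best_equal_length(query, mode, bucket, counts)

    if mode is Mode.CDRH3:
        q3 = qcdrs[2]
        if not q3 or "X" in q3:
            # an 'X' in the loop makes a perfect hash hit unsound; fall back
            bucket = index.by_cdrh3_length.get((query.chain, len(q3)), []) if q3 else []
            counts = [_string_matches(q3, e.cdrs[2]) for e in bucket]
            return _pick_best_equal_length(query, mode, bucket, counts)
        exact = index.cdrh3_exact.get((query.chain, q3))
        if exact:
            first = min(exact, key=lambda e: e.order)
            L = len(q3)
            return MatchResult(
                query_id=query.record_id,
                mode=mode,
                best_value=1.0,
                best_template_id=first.chain.record_id,
                tie_count=len(exact),
                source=first.chain.meta,
                matches=L,
                len_query=L,
                len_template=L,
            )
        bucket = index.by_cdrh3_length.get((query.chain, len(q3)), [])
        counts = [_string_matches(q3, e.cdrs[2]) for e in bucket]
        return _pick_best_equal_length(query, mode, bucket, counts)

    raise ValueError(f"unknown mode: {mode!r}")


def _best_full_chain(query: NumberedChain, index: RepertoireIndex) -> Optional[MatchResult]:
    entries, vocab, mat, lens = index._chain_matrix(query.chain)
    if not entries:
        return None
    lq = len(query)
    qcols = []
    qvals = []
    for pos, aa in query.residues.items():
        col = vocab.get(pos)
        if col is not None and aa != "X":
            qcols.append(col)
            qvals.append(ord(aa))
    if qcols:
        sub = mat[:, np.asarray(qcols)]
        m_vec = (sub == np.asarray(qvals, dtype=np.uint8)).sum(axis=1).astype(np.int64)
    else:
        m_vec = np.zeros(len(entries), dtype=np.int64)
    values = (m_vec / lq + m_vec / lens) / 2.0
    vmax = values.max()
    # floats can blur mathematically equal scores; resolve candidates exactly
    cand = np.flatnonzero(values >= vmax - 1e-9)
    best_exact: Optional[Fraction] = None
    for i in cand:
        ex = (Fraction(int(m_vec[i]), lq) + Fraction(int(m_vec[i]), int(lens[i]))) / 2
        if best_exact is None or ex > best_exact:
            best_exact = ex
    winners = [
        int(i)
        for i in cand
        if (Fraction(int(m_vec[i]), lq) + Fraction(int(m_vec[i]), int(lens[i]))) / 2
        == best_exact
    ]
    first = min(winners, key=lambda i: entries[i].order)
    e = entries[first]
    m = int(m_vec[first])
    return MatchResult(
        query_id=query.record_id,
        mode=Mode.FULL_CHAIN,
        best_value=float(best_exact),
        best_template_id=e.chain.record_id,
        tie_count=len(winners),
        source=e.chain.meta,
        matches=m,
        len_query=lq,
        len_template=len(e.chain),
    )


# ---------------------------------------------------------------------------
# Independent oracle: plain scan, no index
# ---------------------------------------------------------------------------

def exhaustive_best_match(
    query: NumberedChain,
    repertoire: Sequence[NumberedChain],
    mode: Mode,
    scheme: RegionScheme = IMGT_SCHEME,
) -> Optional[MatchResult]:
    """Plain linear scan with the same contract as :func:`best_match`."""
    qcdrs = extract_cdrs(query, scheme)
    best: Optional[tuple[Fraction, int, NumberedChain, IdentityScore]] = None
    ties = 0
    for order, template in enumerate(repertoire):
        if template.chain != query.chain:
            continue
        if mode is Mode.FULL_CHAIN:
            score = positional_identity(query, template)
        elif mode is Mode.CDR_TRIPLET:
            score = cdr_triplet_identity(qcdrs, extract_cdrs(template, scheme))
        else:
            score = cdrh3_identity(qcdrs[2], extract_cdrs(template, scheme)[2])
        if score is None:
            continue
        ex = score.exact
        if best is None or ex > best[0]:
            best = (ex, order, template, score)
            ties = 1
        elif ex == best[0]:
            ties += 1
    if best is None:
        return None
    ex, _, template, score = best
    return MatchResult(
        query_id=query.record_id,
        mode=mode,
        best_value=float(ex),
        best_template_id=template.record_id,
        tie_count=ties,
        source=template.meta,
        matches=score.matches,
        len_query=score.len_query,
        len_template=score.len_template,
    )


# ---------------------------------------------------------------------------
# Streaming profile: one pass, constant memory, optional early-exit bound
# ---------------------------------------------------------------------------

def streaming_best_matches(
    queries: Sequence[NumberedChain],
    repertoire: Iterable[NumberedChain],
    modes: Sequence[Mode],
    scheme: RegionScheme = IMGT_SCHEME,
    early_exit: bool = True,
) -> dict[tuple[str, Mode], Optional[MatchResult]]:
    """Single pass over a repertoire stream updating per-query bests.

    Memory stays proportional to the number of queries.  ``early_exit``
    applies the lossless upper bound m <= min(Lq, Lt), which implies
    value <= (min/Lq + min/Lt)/2: templates that cannot beat the current
    best are skipped without residue comparison.
    """
    qcdrs = {q.record_id: extract_cdrs(q, scheme) for q in queries}
    state: dict[tuple[str, Mode], Optional[tuple[Fraction, NumberedChain, IdentityScore, int]]] = {
        (q.record_id, mode): None for q in queries for mode in modes
    }
    for template in repertoire:
        tcdrs = extract_cdrs(template, scheme)
        lt = len(template)
        for q in queries:
            if q.chain != template.chain:
                continue
            for mode in modes:
                key = (q.record_id, mode)
                cur = state[key]
                if mode is Mode.FULL_CHAIN:
                    if early_exit and cur is not None:
                        lq = len(q)
                        cap = min(lq, lt)
                        bound = (Fraction(cap, lq) + Fraction(cap, lt)) / 2
                        if bound < cur[0]:
                            continue
                    score = positional_identity(q, template)
                elif mode is Mode.CDR_TRIPLET:
                    score = cdr_triplet_identity(qcdrs[q.record_id], tcdrs)
                else:
                    score = cdrh3_identity(qcdrs[q.record_id][2], tcdrs[2])
                if score is None:
                    continue
                ex = score.exact
                if cur is None or ex > cur[0]:
                    state[key] = (ex, template, score, 1)
                elif ex == cur[0]:
                    state[key] = (cur[0], cur[1], cur[2], cur[3] + 1)
    out: dict[tuple[str, Mode], Optional[MatchResult]] = {}
    for (qid, mode), cur in state.items():
        if cur is None:
            out[(qid, mode)] = None
            continue
        ex, template, score, ties = cur
        out[(qid, mode)] = MatchResult(
            query_id=qid,
            mode=mode,
            best_value=float(ex),
            best_template_id=template.record_id,
            tie_count=ties,
            source=template.meta,
            matches=score.matches,
            len_query=score.len_query,
            len_template=score.len_template,
        )
    return out


# ---------------------------------------------------------------------------
# Pairwise identities within a query set
# ---------------------------------------------------------------------------

def pairwise_within_set(queries: Sequence[NumberedChain]) -> np.ndarray:
    """Symmetric full-chain identity matrix with unit diagonal."""
    if len(queries) < 2:
        raise ValueError("need at least 2 chains")
    chains = {q.chain for q in queries}
    if len(chains) != 1:
        raise ValueError("all chains must be of one chain type")
    n = len(queries)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = positional_identity(queries[i], queries[j]).value
            mat[i, j] = mat[j, i] = v
    return mat


def pairs_above(
    queries: Sequence[NumberedChain], threshold: float
) -> list[tuple[str, str, float]]:
    """Unordered pairs whose full-chain identity strictly exceeds threshold."""
    mat = pairwise_within_set(queries)
    out = []
    for i in range(len(queries)):
        for j in range(i + 1, len(queries)):
            if mat[i, j] > threshold:
                out.append((queries[i].record_id, queries[j].record_id, mat[i, j]))
    return out
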