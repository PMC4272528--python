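"""Molecular-tag correction and deduplication.

Reads sharing a (sample, probe, molecular tag) triple are PCR duplicates of
one captured molecule.  Tag correction reassigns tags that are sequencing
errors of a more abundant neighbor; deduplication then keeps exactly one read
per tag family, chosen uniformly at random (seeded), rather than building a
consensus read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GROUP_COLS = ["sample_id", "probe_id", "molecular_tag"]
_CANON_COLS = ["sample_id", "probe_id", "molecular_tag", "base_calls", "base_qualities"]


def _check_tags(reads: pd.DataFrame) -> None:
    if len(reads) == 0:
        return
    lengths = reads["molecular_tag"].str.len()
    if lengths.nunique() > 1:
        raise ValueError("ragged molecular tag lengths")


def _correct_group(tags: list[str], counts: np.ndarray, max_distance: int) -> dict[str, str]:
    """Directional abundance merge within one (sample, probe) group.

    Tags are processed in descending abundance (ties lexicographic); a tag
    within Hamming distance <= max_distance of a strictly more abundant tag is
    reassigned to (the root of) the most abundant such neighbor.  The pass is
    iterated to a fixpoint over the merged families, which makes the whole
    operation idempotent.
    """
    mapping = {t: t for t in tags}
    cur_tags = list(tags)
    cur_counts = np.asarray(counts, dtype=np.int64)
    while True:
        order = sorted(range(len(cur_tags)), key=lambda i: (-cur_counts[i], cur_tags[i]))
        tags_sorted = [cur_tags[i] for i in order]
        counts_sorted = cur_counts[order]
        enc = np.frombuffer("".join(tags_sorted).encode(), dtype=np.uint8).reshape(
            len(tags_sorted), -1
        )
        dist = (enc[:, None, :] != enc[None, :, :]).sum(axis=2)
        root = list(range(len(tags_sorted)))
        changed = False
        for i in range(1, len(tags_sorted)):
            cands = np.nonzero(
                (dist[i, :i] <= max_distance) & (counts_sorted[:i] > counts_sorted[i])
            )[0]
            if cands.size:
                root[i] = root[int(cands[0])]
                changed = True
        if not changed:
            break
        step = {tags_sorted[i]: tags_sorted[root[i]] for i in range(len(tags_sorted))}
        mapping = {t: step[m] for t, m in mapping.items()}
        agg: dict[str, int] = {}
        for i in range(len(tags_sorted)):
            r = tags_sorted[root[i]]
            agg[r] = agg.get(r, 0) + int(counts_sorted[i])
        cur_tags = list(agg)
        cur_counts = np.array([agg[t] for t in cur_tags], dtype=np.int64)
        if len(cur_tags) == 1:
            break
    return mapping


def _group_bounds(sorted_keys: list[np.ndarray], n: int) -> np.ndarray:
    """Start offsets of consecutive key groups in pre-sorted column arrays."""
    new = np.zeros(n, dtype=bool)
    new[0] = True
    for col in sorted_keys:
        new[1:] |= col[1:] != col[:-1]
    return np.flatnonzero(new)


_SORT_KEY = "0123456789abcdef"  # fixed key: content hashes used only for canonical ordering


def _col_hash(df: pd.DataFrame, col: str, hash_key: str = _SORT_KEY) -> np.ndarray:
    return pd.util.hash_pandas_object(df[col], index=False, hash_key=hash_key).to_numpy()


def _canonical_order(df: pd.DataFrame, cols: list[str]) -> tuple[np.ndarray, list[np.ndarray]]:
    """A content-determined row order over ``cols`` (input-order independent).

    Rows are ordered by 64-bit content hashes of the columns, which is fast on
    large string frames and canonical; returns (order, hashed key columns in
    sorted order).
    """
    hashes = [_col_hash(df, c) for c in cols]
    order = np.lexsort(hashes[::-1])
    return order, [h[order] for h in hashes]


def _corrected_tag_column(
    reads: pd.DataFrame,
    max_distance: int,
    order: np.ndarray,
    group_starts: np.ndarray,
) -> np.ndarray:
    """Corrected tag values in original row order, given (sample, probe) grouping."""
    tags_sorted = reads["molecular_tag"].to_numpy()[order]
    ends = np.append(group_starts[1:], len(reads))
    out_tags = reads["molecular_tag"].to_numpy().copy()
    for a, b in zip(group_starts, ends):
        group = tags_sorted[a:b]
        uniq, cnt = np.unique(group, return_counts=True)
        if len(uniq) == 1 or cnt.max() == cnt.min():
            continue  # no strictly-more-abundant neighbor possible
        # prefilter: only tags within reach of a potential parent can merge
        parent_mask = cnt > cnt.min()
        enc = np.frombuffer("".join(uniq).encode(), dtype=np.uint8).reshape(len(uniq), -1)
        dist = (enc[:, None, :] != enc[None, parent_mask, :]).sum(axis=2)
        admissible = (dist <= max_distance) & (cnt[:, None] < cnt[parent_mask][None, :])
        if not admissible.any():
            continue
        involved = (dist <= max_distance).any(axis=1)
        involved |= parent_mask
        sub_tags = [t for t, m in zip(uniq, involved) if m]
        mapping = _correct_group(sub_tags, cnt[involved], max_distance)
        if any(k != v for k, v in mapping.items()):
            out_tags[order[a:b]] = [mapping.get(t, t) for t in group]
    return out_tags


def correct_tags(reads: pd.DataFrame, max_distance: int = 1) -> pd.DataFrame:
    """Return reads with molecular tags corrected within each (sample, probe) group."""
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    _check_tags(reads)
    if max_distance == 0 or len(reads) == 0:
        return reads.copy()
    order, keys = _canonical_order(reads, ["sample_id", "probe_id"])
    starts = _group_bounds(keys, len(reads))
    out = reads.copy()
    out["molecular_tag"] = _corrected_tag_column(reads, max_distance, order, starts)
    return out


def deduplicate(reads: pd.DataFrame, seed: int = 0, method: str = "random") -> pd.DataFrame:
    """Collapse reads to one per (sample, probe, corrected tag) family.

    ``method='random'`` keeps one member read chosen uniformly at random; the
    choice is keyed by a hash of (sample, probe, tag, seed) so the result is
    independent of input ordering.  ``method='consensus'`` instead replaces the
    base calls with the per-position majority over family members (off by
    default).
    """
    if method not in ("random", "consensus"):
        raise ValueError("method must be 'random' or 'consensus'")
    _check_tags(reads)
    if len(reads) == 0:
        return reads.copy()
    order, keys = _canonical_order(reads, _CANON_COLS)
    starts = _group_bounds(keys[:3], len(reads))
    sizes = np.diff(np.append(starts, len(reads)))
    hash_key = format(int(seed) % (2**64), "016x")
    # per-column seeded hashes combined with odd multipliers: the family
    # representative is keyed by (sample, probe, tag, seed), not row position
    heads = reads.iloc[order[starts]]
    h = np.zeros(len(starts), dtype=np.uint64)
    for col, mult in zip(GROUP_COLS, (0x9E3779B97F4A7C15, 0xC2B2AE3D27D4EB4F, 0x165667B19E3779F9)):
        ch = pd.util.hash_pandas_object(heads[col], index=False, hash_key=hash_key).to_numpy()
        h ^= ch * np.uint64(mult)
    pick = starts + (h % sizes.astype(np.uint64)).astype(np.int64)
    result = reads.iloc[order[pick]].reset_index(drop=True)
    if method == "consensus":
        base_sorted = reads["base_calls"].to_numpy()[order]
        consensus_calls = []
        for start, size, row in zip(starts, sizes, result.itertuples()):
            if size == 1:
                consensus_calls.append(row.base_calls)
                continue
            mat = np.frombuffer(
                "".join(base_sorted[start : start + size]).encode(), dtype=np.uint8
            ).reshape(size, -1)
            cols_out = []
            for j in range(mat.shape[1]):
                vals, cnts = np.unique(mat[:, j], return_counts=True)
                cols_out.append(int(vals[np.argmax(cnts)]))  # ties: lexicographically smallest
            consensus_calls.append(bytes(cols_out).decode())
        result = result.assign(base_calls=consensus_calls)
    return result


def group_counts(reads: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Distinct key combinations over ``cols`` and their row counts (fast)."""
    if len(reads) == 0:
        return reads.loc[[], cols], np.array([], dtype=np.int64)
    order, keys = _canonical_order(reads, cols)
    starts = _group_bounds(keys, len(reads))
    sizes = np.diff(np.append(starts, len(reads)))
    return reads.iloc[order[starts]][cols].reset_index(drop=True), sizes


def family_sizes(reads: pd.DataFrame) -> pd.DataFrame:
    """Histogram of tag-family sizes (reads per unique molecule)."""
    _, sizes = group_counts(reads, GROUP_COLS)
    vals, cnts = np.unique(sizes, return_counts=True)
    return pd.DataFrame({"family_size": vals.astype(int), "n_families": cnts})


def correct_and_deduplicate(
    reads: pd.DataFrame,
    max_distance: int = 1,
    seed: int = 0,
    method: str = "random",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tag correction + deduplication in one pass over the read table.

    Produces exactly ``deduplicate(correct_tags(reads, max_distance), seed,
    method)`` (same canonical ordering and representative choice) while
    hashing each column only once, and additionally returns the family-size
    histogram and per-(sample, probe) unique-molecule counts computed from the
    same grouping.
    """
    if method != "random":
        dd = deduplicate(correct_tags(reads, max_distance), seed=seed, method=method)
        corrected = correct_tags(reads, max_distance)
        pairs, cnts = group_counts(dd, ["sample_id", "probe_id"])
        cov = pairs.assign(count=cnts)
        return dd, family_sizes(corrected), cov
    _check_tags(reads)
    if len(reads) == 0:
        empty = reads.copy()
        return empty, pd.DataFrame(columns=["family_size", "n_families"]), pd.DataFrame(
            columns=["sample_id", "probe_id", "count"]
        )
    hs = _col_hash(reads, "sample_id")
    hp = _col_hash(reads, "probe_id")
    order_sp = np.lexsort((hp, hs))
    sp_starts = _group_bounds([hs[order_sp], hp[order_sp]], len(reads))
    if max_distance > 0:
        tags = _corrected_tag_column(reads, max_distance, order_sp, sp_starts)
    else:
        tags = reads["molecular_tag"].to_numpy()
    ht = pd.util.hash_pandas_object(
        pd.Series(tags), index=False, hash_key=_SORT_KEY
    ).to_numpy()
    hc = _col_hash(reads, "base_calls")
    hq = _col_hash(reads, "base_qualities")
    order = np.lexsort((hq, hc, ht, hp, hs))
    keys = [hs[order], hp[order], ht[order]]
    starts = _group_bounds(keys, len(reads))
    sizes = np.diff(np.append(starts, len(reads)))

    vals, cnts = np.unique(sizes, return_counts=True)
    hist = pd.DataFrame({"family_size": vals.astype(int), "n_families": cnts})

    # unique molecules per (sample, probe): count family heads per pair group
    pair_new = np.zeros(len(starts), dtype=bool)
    pair_new[0] = True
    for k in keys[:2]:
        pair_new[1:] |= k[starts[1:]] != k[starts[:-1]]
    pair_starts = np.flatnonzero(pair_new)
    pair_sizes = np.diff(np.append(pair_starts, len(starts)))
    head_rows = order[starts]
    pair_head_rows = head_rows[pair_starts]
    coverage = pd.DataFrame(
        {
            "sample_id": reads["sample_id"].to_numpy()[pair_head_rows],
            "probe_id": reads["probe_id"].to_numpy()[pair_head_rows],
            "count": pair_sizes,
        }
    )

    hash_key = format(int(seed) % (2**64), "016x")
    heads = pd.DataFrame(
        {
            "sample_id": reads["sample_id"].to_numpy()[head_rows],
            "probe_id": reads["probe_id"].to_numpy()[head_rows],
            "molecular_tag": tags[head_rows],
        }
    )
    h = np.zeros(len(starts), dtype=np.uint64)
    for col, mult in zip(GROUP_COLS, (0x9E3779B97F4A7C15, 0xC2B2AE3D27D4EB4F, 0x165667B19E3779F9)):
        ch = pd.util.hash_pandas_object(heads[col], index=False, hash_key=hash_key).to_numpy()
        h ^= ch * np.uint64(mult)
    pick = order[starts + (h % sizes.astype(np.uint64)).astype(np.int64)]
    result = reads.iloc[pick].reset_index(drop=True)
    result["molecular_tag"] = tags[pick]
    return result, hist, coverage
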