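"""Genotype call encoding.

Biallelic calls are coded 1, 0 and -1 for one of the two homozygotes, the
heterozygote and the other homozygote.  The allele that sorts first
lexicographically is the one whose homozygote is coded +1, so the orientation
is deterministic; swapping allele labels flips the sign of the coded column
and leaves the kinship matrix unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = ["encode_genotypes", "MISSING_TOKENS"]

#: genotype-call tokens treated as missing
MISSING_TOKENS = {"NN", "N", "--", "-", "..", ".", "", "00", "0", "NA", "nan"}


def _split_call(call: str) -> tuple[str, str] | None:
    """Return the two allele letters of a call, or None if missing."""
    call = str(call).strip()
    if call in MISSING_TOKENS:
        return None
    if "/" in call or "|" in call:
        parts = call.replace("|", "/").split("/")
    elif len(call) == 2:
        parts = [call[0], call[1]]
    elif len(call) == 1:  # haploid-style shorthand, treated as homozygote
        parts = [call, call]
    else:
        raise ValueError(f"unparseable genotype call {call!r}")
    a, b = parts[0], parts[1]  # case-sensitive: 'A' and 'a' are distinct labels
    if a.upper() in MISSING_TOKENS or b.upper() in MISSING_TOKENS:
        return None
    return a, b


def encode_genotypes(
    raw_calls,
    snp_map=None,
    sample_ids=None,
    missing_policy: str = "mean",
) -> GenotypeMatrix:
    """Code per-marker allele calls into a {1, 0, -1} genotype matrix.

    Parameters
    ----------
    raw_calls
        Marker-major array-like of shape (m, n): one row of n genotype call
        strings (``"AA"``, ``"AG"``, ``"A/G"``...) per marker.
    snp_map
        Optional DataFrame with marker_id / chrom / pos for the input markers.
    missing_policy
        ``"mean"`` imputes missing entries with the marker mean of the
        observed codes; ``"major"`` fills with the most frequent observed code.

    Markers with more than two alleles or with every call missing are rejected
    (listed with reasons under ``provenance["rejected"]``); monomorphic markers
    are kept but flagged.
    """
    if missing_policy not in ("mean", "major"):
        raise ValueError("missing_policy must be 'mean' or 'major'")
    calls = np.asarray(raw_calls, dtype=object)
    if calls.ndim != 2:
        raise ValueError("raw_calls must be 2-D (markers x individuals)")
    m, n = calls.shape
    if snp_map is not None:
        snp_map = pd.DataFrame(snp_map).reset_index(drop=True)
        if len(snp_map) != m:
            raise ValueError("snp_map rows must match number of markers")

    columns, keep_idx, mono, rejected = [], [], [], []
    for j in range(m):
        marker_name = (
            str(snp_map["marker_id"].iloc[j]) if snp_map is not None else f"m{j}"
        )
        codes = np.full(n, np.nan)
        alleles: set[str] = set()
        pairs = []
        for i in range(n):
            pair = _split_call(calls[j, i])
            pairs.append(pair)
            if pair is not None:
                alleles.update(pair)
        if len(alleles) > 2:
            rejected.append((marker_name, f"{len(alleles)} alleles observed"))
            continue
        if not alleles:
            rejected.append((marker_name, "all calls missing"))
            continue
        ordered = sorted(alleles)
        plus = ordered[0]  # lexicographically first allele's homozygote -> +1
        # +1 per 'plus' allele copy, -1 otherwise: 2/0/-2 halved to 1/0/-1
        for i, pair in enumerate(pairs):
            if pair is not None:
                codes[i] = sum(1 if a == plus else -1 for a in pair) / 2.0

        observed = codes[~np.isnan(codes)]
        if observed.size == 0:  # defensive; handled above
            rejected.append((marker_name, "all calls missing"))
            continue
        if np.any(np.isnan(codes)):
            if missing_policy == "mean":
                fill = observed.mean()
            else:
                vals, counts = np.unique(observed, return_counts=True)
                fill = vals[np.argmax(counts)]
            codes = np.where(np.isnan(codes), fill, codes)
        columns.append(codes)
        keep_idx.append(j)
        mono.append(bool(np.unique(observed).size == 1))

    if not columns:
        raise ValueError("no markers survived encoding")
    values = np.column_stack(columns)
    kept_map = snp_map.iloc[keep_idx].reset_index(drop=True) if snp_map is not None else None
    return GenotypeMatrix(
        values=values,
        snp_map=kept_map,
        sample_ids=sample_ids,
        monomorphic=np.asarray(mono, dtype=bool),
        provenance={"missing_policy": missing_policy, "rejected": rejected},
    )
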