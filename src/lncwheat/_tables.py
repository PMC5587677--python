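"""Bundled sequence models and synthetic reference fixtures.

Everything here is generated from closed-form rules so the package ships no
binary data: the biased codon model used to emit coding sequence, the
hexamer log-likelihood-ratio table trained from that model, and short
synthetic rRNA/tRNA-like contaminant and repeat fixtures.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


def codon_weights(bias_strength: float = 1.0) -> dict[str, float]:
    """Probability over the 61 sense codons with a wheat-like GC bias.

    Weights favour G/C at the wobble position and mildly at positions 1-2;
    ``bias_strength`` exponentiates the weight, so 0 gives the uniform
    codon model and larger values sharpen the bias.
    """
    raw = {}
    for codon in SENSE_CODONS:
        gc3 = 1.0 if codon[2] in "GC" else 0.0
        gc12 = sum(b in "GC" for b in codon[:2])
        w = (1.0 + 2.0 * gc3) * (1.0 + 0.35 * gc12)
        raw[codon] = w ** bias_strength
    total = sum(raw.values())
    return {c: w / total for c, w in raw.items()}


@lru_cache(maxsize=8)
def hexamer_table(bias_strength: float = 1.0) -> np.ndarray:
    """Log-likelihood ratio (coding vs uniform background) for all 4096 hexamers.

    A hexamer read in frame from an ORF is a pair of adjacent codons, so the
    coding probability of hexamer c1+c2 is P(c1)P(c2) under the codon model
    (stop-containing hexamers get the background probability, i.e. ratio 0:
    they never occur inside an ORF). Background is the uniform nucleotide
    model, 4**-6 per hexamer. Indexed by base-4 encoding with A=0,C=1,G=2,T=3.
    """
    pc = codon_weights(bias_strength)
    table = np.zeros(4096)
    idx = {b: i for i, b in enumerate(BASES)}
    for c1 in SENSE_CODONS:
        for c2 in SENSE_CODONS:
            h = c1 + c2
            code = 0
            for b in h:
                code = code * 4 + idx[b]
            table[code] = np.log((pc[c1] * pc[c2]) * 4096.0)
    return table


# Synthetic rRNA/tRNA-like contaminant fixtures. These are NOT database
# sequences: they are fixed pseudo-random sequences standing in for the
# Triticum structural-RNA references, bundled so the contaminant screen is
# exercisable offline. Generated once with the formula below and frozen.
def _fixture(name: str, length: int, gc_tail: str = "") -> tuple[str, str]:
    rng = np.random.default_rng(sum(ord(ch) * 37**i for i, ch in enumerate(name)) % (2**31))
    seq = "".join(rng.choice(list("ACGT"), size=length, p=[0.22, 0.28, 0.28, 0.22]))
    return name, seq + gc_tail


CONTAMINANT_FIXTURES: list[tuple[str, str]] = [
    _fixture("synthetic_rRNA_18S_like", 220),
    _fixture("synthetic_rRNA_26S_like", 260),
    _fixture("synthetic_rRNA_5.8S_like", 150),
    _fixture("synthetic_tRNA_Ala_like", 76),
    _fixture("synthetic_tRNA_Gly_like", 74),
    _fixture("synthetic_snoRNA_like", 110),
    _fixture("synthetic_snRNA_U6_like", 105),
    _fixture("synthetic_mito_fragment_like", 300),
]

# Synthetic repeat-library fixtures (transposon-like elements) for the masker.
REPEAT_FIXTURES: list[tuple[str, str]] = [
    _fixture("synthetic_LTR_copia_like", 180),
    _fixture("synthetic_LTR_gypsy_like", 200),
    _fixture("synthetic_MITE_like", 90),
]
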