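"""Built-in synthetic binding-site models.

These are synthetic information models that emulate the motif classes
used throughout the package — splice acceptor/donor, splicing regulatory
factors, transcription factors and RNA-binding proteins — so every
analysis is testable without external downloads. They are NOT the
published human models: each is generated from a hand-written consensus
and per-position conservation profile. Splice-site and SRF models are
built from aligned training sites sampled deterministically from the
profile (so Rsequence and its S.D. are meaningful); TF and RBP models
are exposed as frequency PWMs and converted, mirroring how published
PWMs enter the real analysis (S.D. undefined).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .iminfo import (BASE_INDEX, BASES, FrequencyMatrix,
                     InformationWeightMatrix, build_iwm_from_pwm,
                     build_iwm_from_sites)
from .srfbs import SrfContextRule

_MODEL_SEED = 741852963  # fixed: built-ins must be bit-identical everywhere
_N_TRAINING_SITES = 200

#: consensus, per-position conservation (probability of the consensus base),
#: and anchor offset. Splice models: acceptor anchor = first exon base,
#: donor anchor = first intron base.
_SITE_SPECS = {
    # polypyrimidine tract + yAG | exon start
    "acceptor": {
        "consensus": "TTTTTTTTTTCAGG",
        "conservation": [0.55, 0.55, 0.6, 0.6, 0.65, 0.65, 0.7, 0.7, 0.75,
                         0.6, 0.95, 0.97, 0.97, 0.5],
        "offset": 13, "polarity": "acceptor",
    },
    # exon MAG | GTAAGT intron
    "donor": {
        "consensus": "CAGGTAAGT",
        "conservation": [0.4, 0.6, 0.8, 0.97, 0.97, 0.6, 0.7, 0.8, 0.5],
        "offset": 3, "polarity": "donor",
    },
    "hnRNPA1": {"consensus": "TAGGGT",
                "conservation": [0.85, 0.9, 0.9, 0.9, 0.85, 0.7],
                "offset": 0, "polarity": "motif"},
    "SRSF1": {"consensus": "GGAGGA", "conservation": [0.8] * 6,
              "offset": 0, "polarity": "motif"},
    "SRSF2": {"consensus": "GGCCTC", "conservation": [0.75] * 6,
              "offset": 0, "polarity": "motif"},
    "SRSF5": {"consensus": "ACACGA", "conservation": [0.75] * 6,
              "offset": 0, "polarity": "motif"},
    "SRSF6": {"consensus": "TGCGTC", "conservation": [0.75] * 6,
              "offset": 0, "polarity": "motif"},
    "hnRNPH": {"consensus": "GGGAGG", "conservation": [0.85] * 6,
               "offset": 0, "polarity": "motif"},
    "ELAVL1": {"consensus": "TTTATTT", "conservation": [0.8] * 7,
               "offset": 0, "polarity": "motif"},
    "TIA1": {"consensus": "TTTTTC", "conservation": [0.8] * 6,
             "offset": 0, "polarity": "motif"},
    "PTB": {"consensus": "TCTTCT", "conservation": [0.8] * 6,
            "offset": 0, "polarity": "motif"},
}

_PWM_SPECS = {
    # transcription factors
    "GATA3": ("AGATAAG", 0.9),
    "E2F4": ("TTTGGCGC", 0.85),
    "SP1": ("GGGGCGGGG", 0.85),
    "GABPA": ("CCGGAAGT", 0.85),
    "RUNX3": ("TGTGGTT", 0.85),
    # RNA-binding proteins
    "RBFOX": ("TGCATG", 0.92),
    "SF3B4": ("TTCAAGA", 0.88),
    "CELF4": ("TGTGTG", 0.88),
    "KHDRBS1": ("ATAAAA", 0.85),
    "NCL": ("TCGAGG", 0.85),
}

SRF_FACTORS = ("SRSF1", "SRSF2", "SRSF5", "SRSF6", "hnRNPH", "hnRNPA1",
               "ELAVL1", "TIA1", "PTB")
TF_FACTORS = ("GATA3", "E2F4", "SP1", "GABPA", "RUNX3")
RBP_FACTORS = ("RBFOX", "SF3B4", "CELF4", "KHDRBS1", "NCL")

#: documented splicing roles driving the contextual SRFBS interpretation
SRF_CONTEXT_RULES = {
    "SRSF1": SrfContextRule("SRSF1", "exonic", "enhancer"),
    "SRSF2": SrfContextRule("SRSF2", "exonic", "enhancer"),
    "SRSF5": SrfContextRule("SRSF5", "exonic", "enhancer"),
    "SRSF6": SrfContextRule("SRSF6", "exonic", "enhancer"),
    "hnRNPH": SrfContextRule("hnRNPH", "either", "repressor"),
    "hnRNPA1": SrfContextRule("hnRNPA1", "either", "acceptor-proofreader"),
    "ELAVL1": SrfContextRule("ELAVL1", "either", "enhancer"),
    "TIA1": SrfContextRule("TIA1", "intronic", "enhancer"),
    "PTB": SrfContextRule("PTB", "either", "blocker"),
}

#: transcriptional roles for the TF function filter
TF_ROLES = {"GATA3": "activator", "E2F4": "activator", "SP1": "activator",
            "GABPA": "activator", "RUNX3": "repressor"}


def profile_frequencies(consensus: str, conservation) -> np.ndarray:
    """(L, 4) base frequencies: consensus base gets its conservation,
    the remainder is spread evenly over the other three bases."""
    freq = np.empty((len(consensus), 4))
    for i, (base, c) in enumerate(zip(consensus.upper(), conservation)):
        freq[i, :] = (1.0 - c) / 3.0
        freq[i, BASE_INDEX[base]] = c
    return freq


def sample_sites(freq: np.ndarray, n: int, rng: np.random.Generator
                 ) -> list[str]:
    """Draw n sites from the per-position base distribution."""
    length = freq.shape[0]
    sites = []
    for _ in range(n):
        idx = [rng.choice(4, p=freq[l]) for l in range(length)]
        sites.append("".join(BASES[i] for i in idx))
    return sites


@lru_cache(maxsize=1)
def builtin_models() -> dict[str, InformationWeightMatrix]:
    """All built-in IWMs keyed by factor name. Deterministic."""
    rng = np.random.default_rng(_MODEL_SEED)
    out: dict[str, InformationWeightMatrix] = {}
    for name, spec in _SITE_SPECS.items():
        freq = profile_frequencies(spec["consensus"], spec["conservation"])
        sites = sample_sites(freq, _N_TRAINING_SITES, rng)
        out[name] = build_iwm_from_sites(
            sites, apply_correction=True, polarity=spec["polarity"],
            offset=spec["offset"], model_id=name)
    for name, (consensus, c) in _PWM_SPECS.items():
        freq = profile_frequencies(consensus, [c] * len(consensus))
        pwm = FrequencyMatrix(freq=freq, pseudocount=1e-6)
        out[name] = build_iwm_from_pwm(pwm, model_id=name)
    return out


def splice_models() -> dict[str, InformationWeightMatrix]:
    m = builtin_models()
    return {"acceptor": m["acceptor"], "donor": m["donor"],
            "hnrnpa1": m["hnRNPA1"]}


def srf_models() -> dict[str, InformationWeightMatrix]:
    m = builtin_models()
    return {k: m[k] for k in SRF_FACTORS}


def tf_models() -> dict[str, InformationWeightMatrix]:
    m = builtin_models()
    return {k: m[k] for k in TF_FACTORS}


def rbp_models() -> dict[str, InformationWeightMatrix]:
    m = builtin_models()
    return {k: m[k] for k in RBP_FACTORS}


def factor_table_rows() -> list[tuple[str, str, str]]:
    """(factor, class, role) rows for the factor metadata table."""
    rows = [(f, "SRF", SRF_CONTEXT_RULES[f].role) for f in SRF_FACTORS]
    rows += [(f, "TF", TF_ROLES[f]) for f in TF_FACTORS]
    rows += [(f, "RBP", "binding") for f in RBP_FACTORS]
    return rows
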