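"""File formats, run configuration, checkpoints and the pipeline driver.

All coordinates in files (transmembrane intervals, alignment pairs) are
1-based inclusive; conversion to 0-based happens exactly once, inside
:class:`raretail.scoring.PositionSpecificScheme`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import estimate as est_mod
from .mcmc import Configuration, NullModelPair
from .null_models import (
    Alphabet,
    AlphabetError,
    FixedQueryModel,
    IIDModel,
    PROTEIN_ALPHABET,
    build_tmhmm_layout,
    load_frequencies,
    load_hmm,
    swissprot_frequencies,
)
from .scoring import (
    GapPenalty,
    PositionSpecificScheme,
    blosum62,
    load_matrix,
)
from .wang_landau import (
    ScoreHistogram,
    ScoreWindow,
    WLSchedule,
    WLState,
    production_run,
    wl_estimate,
)

log = logging.getLogger("raretail")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_intervals",
    "RunConfig",
    "load_config",
    "config_hash",
    "save_checkpoint",
    "load_checkpoint",
    "run_pipeline",
]


def read_fasta(path, alphabet: Alphabet = PROTEIN_ALPHABET) -> list[tuple[str, str]]:
    """Read FASTA records; sequences are uppercased and alphabet-validated."""
    from Bio import SeqIO

    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        try:
            alphabet.encode(seq)
        except AlphabetError as exc:
            raise AlphabetError(f"{path}: record {rec.id!r}: {exc}") from None
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """TM intervals as TSV: query_id, start, end (1-based inclusive)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 'query_id start end'")
            qid, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 1 or end < start:
                raise ValueError(f"{path}:{ln}: bad interval ({start}, {end})")
            out.setdefault(qid, []).append((start, end))
    for qid in out:
        out[qid].sort()
    return out


@dataclass
class RunConfig:
    """Everything needed to reproduce one sampling run."""

    mode: str  # RQGS | FQPS | HMM
    query_length: int = 0
    subject_length: int = 0
    s_min: int = 0
    s_max: int = 100
    classes: tuple[int, ...] = (0,)
    n_samples: int = 100_000
    thinning: int = 0  # 0 -> default Lq + Ls
    seed: int = 1
    gap_open: int = 12
    gap_extend: int = 1
    gap_cost_convention: str = "open_plus_len"
    matrix_path: str | None = None  # None -> bundled BLOSUM62
    region_matrix_path: str | None = None
    query_fasta: str | None = None  # FQPS
    intervals_path: str | None = None
    hmm_path: str | None = None  # HMM (None -> built-in TM layout)
    frequencies_path: str | None = None  # None -> bundled composition
    log_phi_initial: float = 0.1
    log_phi_final: float = 0.0002
    flatness_fraction: float = 0.6
    output_dir: str = "raretail_out"

    def __post_init__(self) -> None:
        if self.mode not in ("RQGS", "FQPS", "HMM"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "FQPS" and not self.query_fasta:
            raise ValueError("FQPS mode requires query_fasta")
        if self.mode != "FQPS" and self.query_length < 1:
            raise ValueError("query_length required for random-query modes")
        if self.subject_length < 1:
            raise ValueError("subject_length must be >= 1")
        if self.s_min >= self.s_max:
            raise ValueError("need s_min < s_max")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "classes" in doc:
        doc["classes"] = tuple(doc["classes"])
    return RunConfig(**doc)


def config_hash(config: RunConfig) -> str:
    """Hash of the scientific configuration (the output path is excluded)."""
    doc = asdict(config)
    doc.pop("output_dir", None)
    blob = json.dumps(doc, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_models_and_scheme(config: RunConfig):
    """Materialize the null-model pair and the scoring scheme of a config."""
    alphabet = PROTEIN_ALPHABET
    background = (
        load_frequencies(config.frequencies_path, alphabet)
        if config.frequencies_path
        else swissprot_frequencies(alphabet)
    )
    matrix = (
        load_matrix(config.matrix_path).restrict(alphabet)
        if config.matrix_path
        else blosum62(alphabet)
    )
    gaps = GapPenalty(
        config.gap_open, config.gap_extend, config.gap_cost_convention
    )
    regions: list[tuple[int, int]] = []
    region_matrix = None
    query_length = config.query_length
    if config.mode == "FQPS":
        records = read_fasta(config.query_fasta, alphabet)
        qid, qseq = records[0]
        query_length = len(qseq)
        if config.intervals_path:
            regions = read_intervals(config.intervals_path).get(qid, [])
        query_model = FixedQueryModel(qseq, background)
    elif config.mode == "HMM":
        if config.hmm_path:
            query_model = load_hmm(config.hmm_path)
        else:
            query_model = build_tmhmm_layout(background=background.freqs).hmm
    else:
        query_model = background
    if regions or config.region_matrix_path:
        region_matrix = (
            load_matrix(config.region_matrix_path).restrict(alphabet)
            if config.region_matrix_path
            else matrix
        )
    scheme = PositionSpecificScheme(
        matrix, gaps, region_matrix=region_matrix, query_regions=regions
    )
    models = NullModelPair(query_model, background)
    return models, scheme, query_length


# --------------------------------------------------------------------------
# Checkpoints (structured text; bit-exact resume)
# --------------------------------------------------------------------------


def save_checkpoint(path, config_obj: Configuration, rng: np.random.Generator,
                    step: int, cfg_hash: str, extra: dict | None = None) -> None:
    doc = {
        "config_hash": cfg_hash,
        "step": step,
        "x": [int(v) for v in config_obj.x],
        "y": [int(v) for v in config_obj.y],
        "score": int(config_obj.score),
        "n_tm": int(config_obj.n_tm),
        "log_null": float(config_obj.log_null),
        "rng_state": json.loads(json.dumps(rng.bit_generator.state)),
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_checkpoint(path, cfg_hash: str | None = None):
    doc = json.loads(Path(path).read_text())
    if cfg_hash is not None and doc["config_hash"] != cfg_hash:
        raise ValueError(
            "checkpoint belongs to a different run configuration "
            f"({doc['config_hash']} != {cfg_hash})"
        )
    cfg = Configuration(
        x=np.array(doc["x"], dtype=np.int64),
        y=np.array(doc["y"], dtype=np.int64),
        score=doc["score"],
        n_tm=doc["n_tm"],
        log_null=doc["log_null"],
    )
    rng = np.random.default_rng()
    rng.bit_generator.state = doc["rng_state"]
    return cfg, rng, doc["step"], doc.get("extra", {})


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


def _write_table(path, header: str, rows) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Weight estimation -> production -> reweighting -> fit -> p-values.

    Writes weights, histogram, estimate, fit parameters and a p-value table
    into ``config.output_dir``; every file carries the config hash.  Returns
    a summary dict with the main artifacts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(config)
    models, scheme, query_length = build_models_and_scheme(config)
    window = ScoreWindow(config.s_min, config.s_max, tuple(config.classes))
    schedule = WLSchedule(
        log_phi_initial=config.log_phi_initial,
        log_phi_final=config.log_phi_final,
        flatness_fraction=config.flatness_fraction,
    )
    rng = np.random.default_rng(config.seed)
    thinning = config.thinning or (query_length + config.subject_length)

    log.info("starting weight estimation (hash %s)", h)
    state, chain = wl_estimate(
        models,
        scheme,
        window,
        schedule,
        rng,
        query_length=query_length,
        subject_length=config.subject_length,
    )
    _write_table(
        out / "weights.tsv",
        f"# config={h}\nscore\tn_tm\tlog_w",
        (
            (int(s), int(c), float(state.log_w[ci, bi]))
            for ci, c in enumerate(window.classes)
            for bi, s in enumerate(window.scores)
        ),
    )
    _write_table(
        out / "round_trips.tsv",
        f"# config={h}\ntrip\tstep",
        ((i + 1, s) for i, s in enumerate(state.round_trip_steps)),
    )
    with open(out / "wl_levels.json", "w") as fh:
        json.dump({"config_hash": h, "levels": state.level_log}, fh, indent=1)

    log.info("production run: %d samples, thinning %d", config.n_samples, thinning)
    hist, chain = production_run(
        models,
        scheme,
        window,
        state,
        config.n_samples,
        thinning,
        rng,
        config=chain,
    )
    save_checkpoint(out / "checkpoint.json", chain, rng, state.steps, h)
    _write_table(
        out / "histogram.tsv",
        f"# config={h}\nscore\tn_tm\tcount",
        (
            (int(s), int(c), int(hist.counts[ci, bi]))
            for ci, c in enumerate(window.classes)
            for bi, s in enumerate(window.scores)
        ),
    )

    est = est_mod.reweight(hist)
    _write_table(
        out / "estimate.tsv",
        f"# config={h}\nscore\tn_tm\tlog10_prob\trel_error",
        (
            (
                int(s),
                int(c),
                float(est.log_prob[ci, bi] / np.log(10)),
                float(est.rel_errors[ci, bi]),
            )
            for ci, c in enumerate(window.classes)
            for bi, s in enumerate(window.scores)
            if np.isfinite(est.log_prob[ci, bi])
        ),
    )

    fit = None
    try:
        fit = est_mod.fit_modified_gumbel(
            est,
            query_length=query_length,
            subject_length=config.subject_length,
        )
        meta = {
            "config_hash": h,
            "s0": fit.s0,
            "lambda": fit.lam,
            "lambda2": fit.lam2,
            "K": fit.K,
            "errors": fit.errors,
            "covariance": [[float(v) for v in row] for row in fit.covariance],
            "chi2_reduced": fit.chi2_reduced,
            "fit_window": fit.fit_window,
            "n_bins": fit.n_bins,
            "seed": config.seed,
            "n_samples": config.n_samples,
            "thinning": thinning,
        }
        with open(out / "fit.json", "w") as fh:
            json.dump(meta, fh, indent=1)
    except (ValueError, RuntimeError) as exc:
        log.warning("modified-Gumbel fit failed: %s", exc)

    _write_table(
        out / "pvalues.tsv",
        f"# config={h}\nscore\tpvalue",
        (
            (int(s), est_mod.pvalue(est, int(s), fit=fit))
            for s in window.scores[:: max(window.n_bins // 50, 1)]
        ),
    )
    return {
        "config_hash": h,
        "wl_state": state,
        "histogram": hist,
        "estimate": est,
        "fit": fit,
        "output_dir": str(out),
    }
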