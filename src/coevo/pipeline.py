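"""End-to-end workflows.

Two workflows mirror how co-evolution studies are actually run:

* **intra** — one family: MSA -> gap filter -> reweighting ->
  pseudo-likelihood Potts fit -> APC-corrected contact ranking, and,
  when a reference structure is given, true-positive-rate and
  shortest-path validation against its contact map.
* **inter** — two families: paired MSAs with organism keys -> IPA
  ensemble -> per-pair acceptance-frequency table.

Every run writes its resolved configuration (with a digest) next to its
outputs, and reruns with the same configuration and master seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import alignment as aio
from . import structure as smod
from .ipa import IPAConfig, PairedFamilies, acceptance_frequencies
from .potts import FitConfig, fit_plm
from .scoring import apc_correct, frobenius_scores, rank_contacts
from .synth import consensus_sequence

__all__ = ["RunConfig", "run_intra", "run_inter"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters of a workflow run, with standard defaults."""

    workflow: str = "intra"
    msa: str = ""
    msa_b: str = ""
    structure: str = ""
    out_dir: str = "."
    msa_format: str = ""
    max_gap_fraction: float = 0.10
    identity_threshold: float = 0.90
    lambda_h: float = 0.01
    lambda_J: float = 0.01
    min_separation: int = 5
    top_n_multiplier: float = 1.0
    cutoff: float = 8.5
    n_increment: int = 6
    score_threshold: float = 0.8
    n_runs: int = 200
    pseudocount: float = 0.5
    seed: int = 0

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # where results land is not part of the run
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    def write_resolved(self, out_dir: Path) -> None:
        payload = dataclasses.asdict(self)
        payload["config_digest"] = self.digest()
        with open(out_dir / "resolved_config.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _guess_format(path: str, override: str = "") -> str:
    if override:
        return override
    return "stockholm" if Path(path).suffix in (".sto", ".stk") else "fasta"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def run_intra(config: RunConfig) -> dict:
    """Single-family workflow; returns a report dict and writes TSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln = aio.read_msa(config.msa, _guess_format(config.msa, config.msa_format))
    m0 = aln.M
    aln = aio.filter_gapped_sequences(aln, config.max_gap_fraction)
    logger.info("gap filter: kept %d of %d sequences", aln.M, m0)
    weights = aio.compute_weights(aln, config.identity_threshold)
    logger.info("M=%d L=%d n_eff=%.1f", aln.M, aln.L, weights.n_eff)
    fit_cfg = FitConfig(
        lambda_h=config.lambda_h,
        lambda_J=config.lambda_J,
        identity_threshold=config.identity_threshold,
    )
    model = fit_plm(aln, weights, fit_cfg)
    raw = frobenius_scores(model)
    apc = apc_correct(raw)
    pred = rank_contacts(
        apc,
        min_separation=config.min_separation,
        top_n=aln.L,
        top_n_multiplier=config.top_n_multiplier,
    )
    logger.info("retained %d contacts", len(pred))
    contacts = pd.DataFrame(
        [
            (rank + 1, i + 1, j + 1, raw.S[i, j], s)
            for rank, (i, j, s) in enumerate(pred.pairs)
        ],
        columns=["rank", "i", "j", "raw", "apc"],
    )
    _write_tsv(contacts, out / "contacts.tsv")
    report = {
        "workflow": "intra",
        "M_input": m0,
        "M": aln.M,
        "L": aln.L,
        "n_eff": round(weights.n_eff, 4),
        "retained": len(pred),
        "config_digest": config.digest(),
    }
    if config.structure:
        residues = smod.read_structure(config.structure)
        cmap = smod.contact_map(residues, cutoff=config.cutoff)
        struct_seq = "".join(r.code for r in residues)
        mapping = smod.map_columns(consensus_sequence(aln), struct_seq)
        tpr, curve = smod.true_positive_rate(pred, cmap, mapping)
        sp = smod.shortest_path_classes(pred, cmap, mapping)
        c2r = mapping.column_to_residue
        rows, k = [], 0
        for rank, (i, j, s) in enumerate(pred.pairs):
            if i in c2r and j in c2r:
                a, b = c2r[i], c2r[j]
                rows.append(
                    (rank + 1, i + 1, j + 1, s, bool(cmap.adjacency[a, b]), sp.sp[k])
                )
                k += 1
            else:
                rows.append((rank + 1, i + 1, j + 1, s, None, None))
        validation = pd.DataFrame(
            rows, columns=["rank", "i", "j", "apc", "native", "sp"]
        )
        _write_tsv(validation, out / "validation.tsv")
        report.update(
            {
                "tpr": round(tpr, 6),
                "coverage": round(mapping.coverage, 4),
                "mapping_reliable": mapping.reliable,
                "sp_histogram": {str(k): v for k, v in sorted(sp.histogram().items())},
            }
        )
    config.write_resolved(out)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_inter(config: RunConfig) -> dict:
    """Two-family IPA workflow; returns a report dict and writes the
    acceptance table."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alnA = aio.read_msa(config.msa, _guess_format(config.msa, config.msa_format))
    alnB = aio.read_msa(config.msa_b, _guess_format(config.msa_b, config.msa_format))
    families = PairedFamilies(alnA, alnB)
    if not families.index:
        raise ValueError("the two alignments share no organism")
    ipa_cfg = IPAConfig(
        n_increment=config.n_increment,
        n_runs=config.n_runs,
        pseudocount=config.pseudocount,
        score_threshold=config.score_threshold,
        rng_seed=config.seed,
        identity_threshold=config.identity_threshold,
        plm_config=FitConfig(
            lambda_h=config.lambda_h,
            lambda_J=config.lambda_J,
            identity_threshold=config.identity_threshold,
        ),
    )
    table = acceptance_frequencies(families, ipa_cfg)
    rows = [
        (i + 1, j + 1, table.counts.get((i, j), 0), freq, table.mean_score[(i, j)])
        for i, j, freq in table.ranked()
    ]
    df = pd.DataFrame(
        rows, columns=["i", "j", "accept_count", "accept_freq", "mean_score"]
    )
    _write_tsv(df, out / "acceptance.tsv")
    report = {
        "workflow": "inter",
        "n_runs": table.n_runs,
        "n_accepted_pairs": len(table.counts),
        "config_digest": config.digest(),
    }
    config.write_resolved(out)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
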