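"""Stage orchestration and JSON report assembly.

Every stage writes a flat JSON report that embeds the fully resolved
configuration and the seed, so a rerun with the same inputs and seed is
byte-identical (no timestamps inside reports; timings go to the log only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import distance as _distance
from . import homology as _homology
from . import profiles as _profiles
from . import redundancy as _redundancy
from . import summary as _summary

logger = logging.getLogger("genecontent")

STAGES = ("profile", "redundancy", "overrep", "shared", "distance", "summary")


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run."""

    out_dir: str
    stages: tuple[str, ...] = STAGES
    seed: int = 42
    assignments: str | None = None
    genome_ids: tuple[str, ...] = ()
    multi_policy: str = "per_pair"
    top: int | None = None
    proteomes: tuple[str, ...] = ()
    max_evalue: float = 1e-5
    min_identity_pct: float = 30.0
    genome_fastas: tuple[str, ...] = ()
    word_size: int = 11
    xdrop: int = 20
    min_length: int = 50
    both_strands: bool = False
    gff3: str | None = None
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        for st in self.stages:
            if st not in STAGES:
                raise ValueError(f"unknown stage {st!r}")
        for path in filter(None, [self.assignments, self.gff3, *self.proteomes, *self.genome_fastas]):
            if not Path(path).exists():
                raise FileNotFoundError(path)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _write_report(out_dir: Path, name: str, payload: dict, config: RunConfig) -> Path:
    report = {"stage": name, "seed": config.seed, "config": config.to_dict(), "result": payload}
    path = out_dir / f"{name}.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the requested stages; returns stage name -> report path.

    Stage wiring: ``profile`` parses the assignment table into per-genome
    abundance profiles; ``redundancy`` and ``overrep`` consume those
    profiles; ``shared`` runs the homolog/Venn analysis over the given
    proteomes; ``distance`` runs the HSP finder plus coverage/identity
    formulas over the first two genome FASTAs; ``summary`` computes genome
    summary statistics per FASTA.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    combined: dict[str, dict] = {}

    profiles_by_genome: dict[str, _profiles.AbundanceProfile] = {}

    def need_profiles():
        if profiles_by_genome:
            return
        if config.assignments is None:
            raise ValueError("profile/redundancy/overrep stages need --assignments")
        rows = _profiles.read_assignments(config.assignments)
        genome_ids = config.genome_ids or tuple(dict.fromkeys(a.genome_id for a in rows))
        for gid in genome_ids:
            profiles_by_genome[gid] = _profiles.build_profile(
                rows, gid, multi_policy=config.multi_policy
            )

    for stage in config.stages:
        t0 = time.monotonic()
        logger.info("stage %s: start", stage)

        if stage == "profile":
            need_profiles()
            payload = {}
            for gid, prof in profiles_by_genome.items():
                series = _profiles.rank_frequencies(prof, top=config.top)
                series.to_tsv(out_dir / f"rank_frequencies_{gid}.tsv")
                payload[gid] = {
                    "N": prof.N,
                    "S": prof.S,
                    "rank_frequencies_tsv": f"rank_frequencies_{gid}.tsv",
                }
        elif stage == "redundancy":
            need_profiles()
            payload = {
                gid: _redundancy.redundancy_report(prof).to_dict()
                for gid, prof in profiles_by_genome.items()
            }
        elif stage == "overrep":
            need_profiles()
            payload = {}
            for gid, prof in profiles_by_genome.items():
                table = _redundancy.overlay_table(prof, top=config.top)
                tsv = out_dir / f"overrep_overlay_{gid}.tsv"
                table.to_csv(tsv, sep="\t", index=False, lineterminator="\n")
                payload[gid] = {
                    "n_overrepresented": int(table["overrepresented"].sum()),
                    "overlay_tsv": tsv.name,
                }
        elif stage == "shared":
            if len(config.proteomes) not in (2, 3):
                raise ValueError("shared stage needs two or three --proteome files")
            params = _homology.HomologyParams(
                max_evalue=config.max_evalue, min_identity_pct=config.min_identity_pct
            )
            names = tuple(Path(p).stem for p in config.proteomes)
            if len(config.proteomes) == 3:
                part = _homology.venn3(*config.proteomes, params=params, genome_names=names)
                payload = part.to_dict()
            else:
                fwd = _homology.homologs(config.proteomes[0], config.proteomes[1], params)
                rev = _homology.homologs(config.proteomes[1], config.proteomes[0], params)
                payload = {
                    "genome_names": list(names),
                    f"{names[0]}_with_homolog_in_{names[1]}": len(fwd),
                    f"{names[1]}_with_homolog_in_{names[0]}": len(rev),
                }
        elif stage == "distance":
            if len(config.genome_fastas) != 2:
                raise ValueError("distance stage needs exactly two genome FASTAs")
            result, hsps = _distance.genome_pair_distance(
                config.genome_fastas[0],
                config.genome_fastas[1],
                word_size=config.word_size,
                xdrop=config.xdrop,
                min_length=config.min_length,
                both_strands=config.both_strands,
            )
            _distance.write_hsps_tsv(hsps, out_dir / "hsps.tsv")
            payload = result.to_dict()
            payload["hsps_tsv"] = "hsps.tsv"
        elif stage == "summary":
            if not config.genome_fastas:
                raise ValueError("summary stage needs at least one genome FASTA")
            payload = {}
            for path in config.genome_fastas:
                gff3 = config.gff3 if len(config.genome_fastas) == 1 else None
                payload[Path(path).stem] = _summary.genome_summary(path, gff3=gff3).to_dict()
        else:  # pragma: no cover - guarded by validate()
            raise AssertionError(stage)

        written[stage] = _write_report(out_dir, stage, payload, config)
        combined[stage] = payload
        logger.info("stage %s: done in %.3fs", stage, time.monotonic() - t0)

    written["combined"] = _write_report(out_dir, "combined", combined, config)
    return written
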