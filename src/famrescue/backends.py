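"""Command-template adapter: drive an external structure predictor.

The adapter satisfies the :class:`famrescue.rescue.PredictionBackend` contract
by materializing a prediction request on disk -- a FASTA with the query
sequence and a directory of template PDB files -- invoking a user-supplied
command template, and reading the predicted model back.  It knows nothing
about the predictor beyond the command line; ColabFold-style tools that accept
a FASTA, a custom template directory and an MSA switch fit directly.

Command placeholders: ``{fasta}``, ``{template_dir}``, ``{out_dir}``,
``{msa_flag}`` (expands to ``msa_mode_flag`` when the MSA is enabled, else to
``single_sequence_flag``).  The predictor must leave exactly one ``*.pdb`` (or
``*.cif``) model in the output directory.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from .exceptions import BackendContractError, FormatError
from .model_io import mean_plddt, read_model, write_model
from .rescue import PredictionRequest, PredictionResult


@dataclass
class CommandBackend:
    """Run an external predictor through a shell command template."""

    command_template: str
    msa_mode_flag: str = ""
    single_sequence_flag: str = "--msa-mode single_sequence"
    workdir: Path | None = None
    domain_spans: dict[str, tuple[int, int]] | None = None
    timeout: float | None = None

    def predict(self, request: PredictionRequest) -> PredictionResult:
        if request.mode != "no_template_msa" and not request.templates:
            raise BackendContractError(
                f"{request.mode} request for {request.protein_id} has no templates"
            )
        base = Path(
            tempfile.mkdtemp(prefix=f"{request.protein_id}_", dir=self.workdir)
        )
        fasta = base / "query.fasta"
        fasta.write_text(f">{request.protein_id}\n{request.sequence}\n")
        template_dir = base / "templates"
        template_dir.mkdir()
        for t in request.templates:
            write_model(t, template_dir / f"{t.protein_id}.pdb", format="pdb")
        out_dir = base / "out"
        out_dir.mkdir()
        cmd = self.command_template.format(
            fasta=fasta,
            template_dir=template_dir,
            out_dir=out_dir,
            msa_flag=self.msa_mode_flag
            if request.msa_enabled
            else self.single_sequence_flag,
        )
        proc = subprocess.run(
            shlex.split(cmd), capture_output=True, text=True, timeout=self.timeout
        )
        if proc.returncode != 0:
            raise BackendContractError(
                f"predictor command failed ({proc.returncode}): {proc.stderr[-500:]}"
            )
        produced = sorted(out_dir.glob("*.pdb")) + sorted(out_dir.glob("*.cif"))
        if len(produced) != 1:
            raise BackendContractError(
                f"expected one model in {out_dir}, found {len(produced)}"
            )
        try:
            model = read_model(produced[0])
        except FormatError as exc:
            raise BackendContractError(f"unreadable predictor output: {exc}") from exc
        span = (self.domain_spans or {}).get(
            request.protein_id, (1, len(model))
        )
        return PredictionResult(
            protein_id=request.protein_id,
            mode=request.mode,
            model=model,
            mean_plddt=model.mean_plddt,
            domain_plddt=mean_plddt(model, span),
        )
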