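"""Volume bookkeeping: voxel counts and relative volumes per compartment.

Beetle-tunnel volume is reported separately for the bark, the wood and the
complete log, as a percentage of the respective compartment including the
excavated space itself:

    relative tunnel volume (total) = tunnels / (bark + wood + tunnels) x 100

Decay volume is reported relative to the wood compartment. Larvae occupy
excavated space and are counted toward tunnel volume when requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .labels import Label, LabelVolume


@dataclass
class VolumeSummary:
    """Voxel counts and relative volumes [%] for one log."""

    voxel_volume_mm3: float
    tunnel_bark_vox: int
    tunnel_wood_vox: int
    bark_vox: int
    wood_vox: int
    larva_vox: int = 0
    crack_vox: int = 0
    drilling_vox: int = 0
    decay_vox: int = 0
    log_id: str = ""
    #: whether larva voxels were folded into the tunnel counts above
    larvae_counted_as_tunnel: bool = False

    @property
    def tunnel_total_vox(self) -> int:
        return self.tunnel_bark_vox + self.tunnel_wood_vox

    @property
    def tunnel_bark_percent(self) -> float:
        denom = self.bark_vox + self.tunnel_bark_vox
        return 100.0 * self.tunnel_bark_vox / denom if denom else 0.0

    @property
    def tunnel_wood_percent(self) -> float:
        denom = self.wood_vox + self.tunnel_wood_vox
        return 100.0 * self.tunnel_wood_vox / denom if denom else 0.0

    @property
    def tunnel_total_percent(self) -> float:
        denom = self.bark_vox + self.wood_vox + self.tunnel_total_vox
        return 100.0 * self.tunnel_total_vox / denom if denom else 0.0

    @property
    def decay_percent(self) -> float:
        """Decayed wood as % of the wood compartment (decay is wood)."""
        denom = self.wood_vox + self.decay_vox
        return 100.0 * self.decay_vox / denom if denom else 0.0

    def to_row(self) -> dict:
        """Flat dict for tidy CSV export (one row per log)."""
        return {
            "log_id": self.log_id,
            "voxel_volume_mm3": self.voxel_volume_mm3,
            "bark_vox": self.bark_vox,
            "wood_vox": self.wood_vox,
            "tunnel_bark_vox": self.tunnel_bark_vox,
            "tunnel_wood_vox": self.tunnel_wood_vox,
            "larva_vox": self.larva_vox,
            "crack_vox": self.crack_vox,
            "drilling_vox": self.drilling_vox,
            "decay_vox": self.decay_vox,
            "tunnel_bark_percent": self.tunnel_bark_percent,
            "tunnel_wood_percent": self.tunnel_wood_percent,
            "tunnel_total_percent": self.tunnel_total_percent,
            "decay_percent": self.decay_percent,
        }


def summarize_labels(
    labels: LabelVolume,
    include_larvae: bool = False,
    log_id: str = "",
) -> VolumeSummary:
    """Exact voxel counts and relative fractions from a label volume.

    This is the ground-truth twin of the segmentation pipeline's output:
    applied to a phantom's label volume it yields the true compartment
    fractions the pipeline is benchmarked against.

    Parameters
    ----------
    include_larvae
        Count larva voxels toward the tunnel volume of their compartment
        (larvae sit inside excavated galleries). Larvae are assigned to the
        bark compartment only when they touch no wood; phantom larvae are
        always attached to galleries in wood, so they count as wood tunnel.
    """
    c = labels.counts()
    tunnel_bark = c[Label.TUNNEL_BARK]
    tunnel_wood = c[Label.TUNNEL_WOOD]
    if include_larvae:
        tunnel_wood += c[Label.LARVA]
    return VolumeSummary(
        voxel_volume_mm3=labels.voxel_volume_mm3,
        tunnel_bark_vox=tunnel_bark,
        tunnel_wood_vox=tunnel_wood,
        bark_vox=c[Label.BARK],
        wood_vox=c[Label.WOOD],
        larva_vox=c[Label.LARVA],
        crack_vox=c[Label.CRACK],
        drilling_vox=c[Label.DRILLING],
        decay_vox=c[Label.DECAY],
        log_id=log_id,
        larvae_counted_as_tunnel=include_larvae,
    )


def summaries_to_frame(summaries: list[VolumeSummary]) -> pd.DataFrame:
    """Stack per-log summaries into a tidy DataFrame (one row per log)."""
    return pd.DataFrame([s.to_row() for s in summaries])
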