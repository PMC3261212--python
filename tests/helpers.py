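"""Shared test utilities (not a test module)."""

from bacmap import anchoring, pooling


def screen_markers(ds, pmap, seed=0, v=90, k=4):
    """Run the pooled screen for every simulated marker against a map.

    Superpool positives are derived from the ground-truth marker-bearing
    clones; deconvolution and anchoring then run exactly as they would on
    real band data.
    """
    n_plates = max(c.plate for c in ds.clones)
    design = pooling.generate_design(n_qpp=n_plates * 4, v=v, k=k, seed=seed)
    qpp_members = {}
    for c in ds.clones:
        qpp_members.setdefault(c.qpp, []).append(c.clone_id)
    anchors = []
    for mk in ds.markers:
        true_clones = ds.true_marker_clones(mk.marker_id)
        pos_q = {
            q for q, members in qpp_members.items()
            if any(c in true_clones for c in members)
        }
        pos_sp = set()
        for q in pos_q:
            pos_sp |= design.assignment[q]
        deconv = pooling.deconvolute(pos_sp, design)
        anchors.append(anchoring.keymaps_anchor(mk, deconv, pmap, ds.layout))
    return anchors
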