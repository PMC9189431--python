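cell_channel: 1
cell_marker_mode: membrane
cell_smooth_sigma_um: [1.0, 1.0, 1.0]
cell_threshold_method: triangle
detection_threshold: 0.1
detector: advanced
detector_scale_um: 1.5
distance_threshold: 0.5
expression_channels: []
lambda_reg: 1.0
normalisation_channel: null
nucleus_channel: 0
nucleus_smooth_sigma_um: [0.5, 0.3, 0.3]
nucleus_threshold_method: otsu
output_dir: embryoseg_out
seed: 42
spacing_override_um: null
tophat_downsize: 4
tophat_radius_um: 4.0
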