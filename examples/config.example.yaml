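# Example session configuration (YAML; JSON is accepted too).
# Every field below is spelled out at its default value.
#
# camera: view-camera resolution (px) and viewing angles (deg); the
#   pixel-to-degree conversion is fov/resolution per axis.
# markers: template image paths for the four windshield markers and the
#   alpha:beta inter-marker spacing ratio used to extrapolate the reference
#   position of the outermost marker (invisible while facing forward).
# zones: ordered gaze-area rectangles in gaze degrees; first match wins.
#   '.inf' / '-.inf' mark unbounded sides.
# frame_rate: view-camera frame rate (Hz), used to timestamp tracked frames.
# similarity_threshold: minimum normalized cross-correlation score in [0, 1]
#   for an accepted marker detection.
# bin_width: gaze histogram bin width (deg).
# range_threshold: fraction of the peak marginal bin count a bin must reach
#   to count toward the gaze range (0.05 = 5 %).
# extension_gain: search-window extension per unit of inter-frame marker
#   displacement.
# search_margin: tracking window half-size, in template widths/heights.
camera:
  width: 640
  height: 480
  fov_x: 60.0
  fov_y: 45.0
markers:
  templates:
    1: templates/marker1.png
    2: templates/marker2.png
    3: templates/marker3.png
    4: templates/marker4.png
  alpha: 220.0
  beta: 220.0
zones:
- label: front
  x_min: -20
  x_max: 20
  y_min: -20
  y_max: 20
- label: meter
  x_min: -20
  x_max: 20
  y_min: '-.inf'
  y_max: -20
- label: rearview mirror
  x_min: -20
  x_max: 20
  y_min: 20
  y_max: '.inf'
- label: left mirror
  x_min: -55
  x_max: -25
  y_min: -30
  y_max: -10
- label: right mirror
  x_min: 25
  x_max: 55
  y_min: -30
  y_max: -10
- label: left back
  x_min: '-.inf'
  x_max: -90
  y_min: '-.inf'
  y_max: '.inf'
- label: right back
  x_min: 90
  x_max: '.inf'
  y_min: '-.inf'
  y_max: '.inf'
- label: left
  x_min: '-.inf'
  x_max: -20
  y_min: '-.inf'
  y_max: '.inf'
- label: right
  x_min: 20
  x_max: '.inf'
  y_min: '-.inf'
  y_max: '.inf'
frame_rate: 30.0
similarity_threshold: 0.7
bin_width: 5.0
range_threshold: 0.05
extension_gain: 1.5
search_margin: 2.0
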