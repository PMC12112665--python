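{
  "version": "zones_468_v1",
  "mesh_size": 468,
  "left_eye_index": 33,
  "right_eye_index": 263,
  "zones": {
    "AU1": {
      "name": "inner brow raiser (space between the eyebrows)",
      "indices": [66, 107, 55, 65, 296, 336, 285, 295],
      "color_tag": "yellow"
    },
    "AU4": {
      "name": "brow lowerer (glabella / nasion column)",
      "indices": [8, 9, 168, 6],
      "color_tag": "orange"
    },
    "AU6": {
      "name": "cheek raiser (infraorbital triangle)",
      "indices": [117, 118, 119, 100, 346, 347, 348, 329],
      "color_tag": "red"
    },
    "AU7": {
      "name": "lid tightener (lower eyelid)",
      "indices": [145, 144, 153, 374, 373, 380],
      "color_tag": "purple"
    },
    "AU9": {
      "name": "nose wrinkler (nasal sidewalls)",
      "indices": [48, 115, 220, 278, 344, 440],
      "color_tag": "green"
    },
    "AU10": {
      "name": "upper lip raiser (philtrum ridge)",
      "indices": [37, 0, 267, 39, 269],
      "color_tag": "pink"
    },
    "AU15": {
      "name": "lip corner depressor (mouth corners)",
      "indices": [61, 291, 76, 306],
      "color_tag": "blue"
    },
    "AU17": {
      "name": "chin raiser (mentalis region)",
      "indices": [18, 200, 199, 175],
      "color_tag": "cyan"
    },
    "AU43": {
      "name": "eye closure (upper-lid gap)",
      "indices": [159, 158, 386, 385],
      "color_tag": "gray"
    },
    "AU44": {
      "name": "squint (periocular ring)",
      "indices": [130, 247, 359, 467],
      "color_tag": "magenta"
    }
  }
}
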