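{
  "comment": "Operator warnings and patient guidance keyed by criterion id.",
  "catalog": {
    "bev_limit": {
      "operator": "Back-extrapolated volume exceeds the limit: the blast did not start fast enough.",
      "patient": "Blast the air out immediately and as hard as you can, without easing into it."
    },
    "fev1_measurable": {
      "operator": "Recording ended within the first second: FEV1 cannot be measured.",
      "patient": "Keep blowing for at least a few seconds once you start."
    },
    "cough_first_second": {
      "operator": "Cough detected in the first second: FEV1 is not reportable from this maneuver.",
      "patient": "Try to avoid coughing, especially right after you start blowing."
    },
    "glottic_closure_first_second": {
      "operator": "Glottic closure in the first second: FEV1 is not reportable from this maneuver.",
      "patient": "Keep your throat open and keep the air flowing smoothly."
    },
    "glottic_closure_any": {
      "operator": "Glottic closure detected: FVC is underestimated in this maneuver.",
      "patient": "Keep pushing the air out steadily until asked to stop; do not hold your breath."
    },
    "flutter_first_second": {
      "operator": "Flow oscillation (possible obstructed mouthpiece or device fault) in the first second.",
      "patient": "Keep your tongue and teeth clear of the mouthpiece."
    },
    "flutter_any": {
      "operator": "Sustained flow oscillation: check the mouthpiece and the spirometer.",
      "patient": "Keep your tongue and teeth clear of the mouthpiece."
    },
    "extra_breath_first_second": {
      "operator": "Extra breath taken in the first second of the maneuver.",
      "patient": "Take one deep breath in, then blow it all out in a single effort without breathing in again."
    },
    "extra_breath_any": {
      "operator": "Extra breath taken during the maneuver: the volume record is corrupted.",
      "patient": "Do not breathe in again until the test is over."
    },
    "hesitant_start": {
      "operator": "Hesitant start: too much volume was exhaled before the blast.",
      "patient": "Start the blast immediately at full effort."
    },
    "variable_flow": {
      "operator": "Peak flow was reached late: submaximal initial effort.",
      "patient": "Blow out as hard and as fast as you can right from the start."
    },
    "eofe": {
      "operator": "End of forced expiration not reached (no plateau, short FET, FVC not repeatable).",
      "patient": "Keep squeezing the air out until you are completely empty."
    },
    "early_termination": {
      "operator": "Expiration was terminated early.",
      "patient": "Keep blowing until asked to stop, even when it feels like nothing is coming out."
    },
    "repeat_maneuver": {
      "operator": "Session quality below grade C: obtain additional maneuvers.",
      "patient": "We need to repeat the test; please try one more time."
    }
  }
}
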