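{"pid": "W", "recorded_at": 0.0, "t": 0.0, "x": 141.0, "y": 387.1}
{"pid": "W", "recorded_at": 0.0, "t": 0.59, "x": 318.0, "y": 426.7}
{"pid": "W", "recorded_at": 0.0, "t": 1.0, "x": 142.0, "y": 379.1}
{"pid": "W", "recorded_at": 0.0, "t": 1.46, "x": 316.0, "y": 402.6}
{"pid": "W", "recorded_at": 0.0, "t": 1.77, "x": 162.0, "y": 410.3}
{"pid": "W", "recorded_at": 0.0, "t": 2.31, "x": 338.0, "y": 406.9}
{"pid": "W", "recorded_at": 0.0, "t": 2.66, "x": 153.0, "y": 389.8}
{"pid": "W", "recorded_at": 0.0, "t": 3.12, "x": 345.0, "y": 426.3}
{"pid": "W", "recorded_at": 0.0, "t": 3.79, "x": 157.0, "y": 382.0}
{"pid": "W", "recorded_at": 0.0, "t": 4.14, "x": 327.0, "y": 401.2}
{"pid": "W", "recorded_at": 0.0, "t": 4.49, "x": 137.0, "y": 384.8}
{"pid": "W", "recorded_at": 0.0, "t": 4.87, "x": 330.0, "y": 409.4}
{"pid": "W", "recorded_at": 0.0, "t": 5.47, "x": 142.0, "y": 398.1}
{"pid": "W", "recorded_at": 0.0, "t": 5.78, "x": 313.0, "y": 407.4}
{"pid": "W", "recorded_at": 0.0, "t": 6.38, "x": 146.0, "y": 397.4}
{"pid": "W", "recorded_at": 0.0, "t": 6.75, "x": 312.0, "y": 424.3}
{"pid": "W", "recorded_at": 0.0, "t": 7.32, "x": 151.0, "y": 387.7}
{"pid": "W", "recorded_at": 0.0, "t": 7.64, "x": 333.0, "y": 419.6}
{"pid": "W", "recorded_at": 0.0, "t": 8.25, "x": 141.0, "y": 408.1}
{"pid": "W", "recorded_at": 0.0, "t": 8.82, "x": 347.0, "y": 427.4}
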