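{
 "type": "FeatureCollection",
 "features": [
  {
   "type": "Feature",
   "properties": {
    "region_id": 1
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -150,
       15
      ],
      [
       -120,
       15
      ],
      [
       -120,
       35
      ],
      [
       -150,
       35
      ],
      [
       -150,
       15
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "region_id": 2
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -120,
       15
      ],
      [
       -100,
       15
      ],
      [
       -100,
       35
      ],
      [
       -120,
       35
      ],
      [
       -120,
       15
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "region_id": 3
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -100,
       15
      ],
      [
       -90,
       15
      ],
      [
       -90,
       35
      ],
      [
       -100,
       35
      ],
      [
       -100,
       15
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "region_id": 4
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -90,
       15
      ],
      [
       -75,
       15
      ],
      [
       -75,
       35
      ],
      [
       -90,
       35
      ],
      [
       -90,
       15
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "region_id": 5
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -150,
       -5
      ],
      [
       -120,
       -5
      ],
      [
       -120,
       15
      ],
      [
       -150,
       15
      ],
      [
       -150,
       -5
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "region_id": 6
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -120,
       -5
      ],
      [
       -100,
       -5
      ],
      [
       -100,
       15
      ],
      [
       -120,
       15
      ],
      [
       -120,
       -5
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "region_id": 7
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -100,
       -5
      ],
      [
       -90,
       -5
      ],
      [
       -90,
       15
      ],
      [
       -100,
       15
      ],
      [
       -100,
       -5
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "region_id": 8
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -90,
       -5
      ],
      [
       -75,
       -5
      ],
      [
       -75,
       15
      ],
      [
       -90,
       15
      ],
      [
       -90,
       -5
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "region_id": 9
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -150,
       -25
      ],
      [
       -120,
       -25
      ],
      [
       -120,
       -5
      ],
      [
       -150,
       -5
      ],
      [
       -150,
       -25
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "region_id": 10
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -120,
       -25
      ],
      [
       -100,
       -25
      ],
      [
       -100,
       -5
      ],
      [
       -120,
       -5
      ],
      [
       -120,
       -25
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "region_id": 11
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -100,
       -25
      ],
      [
       -90,
       -25
      ],
      [
       -90,
       -5
      ],
      [
       -100,
       -5
      ],
      [
       -100,
       -25
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "region_id": 12
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       -90,
       -25
      ],
      [
       -75,
       -25
      ],
      [
       -75,
       -5
      ],
      [
       -90,
       -5
      ],
      [
       -90,
       -25
      ]
     ]
    ]
   }
  }
 ]
}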