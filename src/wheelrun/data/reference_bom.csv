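name,category,unit_cost_usd,quantity,line_total_usd
Creality Ender 3 3D printer,MAJOR_EQUIPMENT,189.00,1,189.00
Mini PC (12 GB + 256 GB / Intel Celeron N5105),MAJOR_EQUIPMENT,169.99,1,169.99
Arduino UNO REV 3,MAJOR_EQUIPMENT,28.99,3,86.97
Soldering station,MAJOR_EQUIPMENT,74.99,1,74.99
PETG filament (1.75 mm 1 kg),MAJOR_EQUIPMENT,16.99,4,67.96
Dremel 7760 Lite rotary tool,MAJOR_EQUIPMENT,64.00,1,64.00
Adafruit assembled data logging shield for Arduino,MAJOR_EQUIPMENT,13.95,3,41.85
Heat gun (1350 W),MAJOR_EQUIPMENT,29.40,1,29.40
16 GB SD card (2 pcs),MAJOR_EQUIPMENT,13.79,2,27.58
Arduino pin headers (112 pcs),MAJOR_EQUIPMENT,12.98,1,12.98
Self-adjusting wire stripper,MAJOR_EQUIPMENT,9.99,1,9.99
Needle-nose pliers (6 in),MAJOR_EQUIPMENT,8.99,1,8.99
Brass extruder nozzles (24 pcs),MAJOR_EQUIPMENT,8.49,1,8.49
USB SD card reader,MAJOR_EQUIPMENT,7.99,1,7.99
CR1220 3V lithium coin cell battery (5 pack),MAJOR_EQUIPMENT,5.95,1,5.95
Plastic magnetic reed switch (14 mm 10 pcs),CONSUMABLE,9.99,5,49.95
Ball bearing (10x26x8 mm double sealed 10 pcs),CONSUMABLE,8.99,5,44.95
Pluggable LED wire connectors (20-24 AWG 12 pcs),CONSUMABLE,7.99,5,39.95
Electrical wire 24/2 AWG (32.8 ft),CONSUMABLE,9.99,3,29.97
Round magnets 6x2 mm (25 pcs),CONSUMABLE,6.99,4,27.96
Tin lead rosin core solder wire (0.8 mm 50 g),CONSUMABLE,8.99,2,17.98
Jumper wires (120 pcs),CONSUMABLE,6.98,1,6.98
Super glue (2 g 4 pcs),CONSUMABLE,4.79,1,4.79
Vinyl electrical tape (3/4 in x 66 ft),CONSUMABLE,2.78,1,2.78
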