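logmar,snellen
-0.341,10+2
-0.321,10+1
-0.301,10
-0.281,10-1
-0.261,10-2
-0.2441,12.5+2
-0.2241,12.5+1
-0.2041,12.5
-0.1841,12.5-1
-0.1641,12.5-2
-0.1369,16+2
-0.1169,16+1
-0.0969,16
-0.0769,16-1
-0.0569,16-2
-0.04,20+2
-0.02,20+1
0,20
0.02,20-1
0.04,20-2
0.0569,25+2
0.0769,25+1
0.0969,25
0.1169,25-1
0.1369,25-2
0.1641,32+2
0.1841,32+1
0.2041,32
0.2241,32-1
0.2441,32-2
0.261,40+2
0.281,40+1
0.301,40
0.321,40-1
0.341,40-2
0.3579,50+2
0.3779,50+1
0.3979,50
0.4179,50-1
0.4379,50-2
0.4583,63+2
0.4783,63+1
0.4983,63
0.5183,63-1
0.5383,63-2
0.5621,80+2
0.5821,80+1
0.6021,80
0.6221,80-1
0.6421,80-2
0.659,100+2
0.679,100+1
0.699,100
0.719,100-1
0.739,100-2
0.7559,125+2
0.7759,125+1
0.7959,125
0.8159,125-1
0.8359,125-2
0.8631,160+2
0.8831,160+1
0.9031,160
0.9231,160-1
0.9431,160-2
0.96,200+2
0.98,200+1
1,200
1.02,200-1
1.04,200-2
1.261,400+2
1.281,400+1
1.301,400
1.321,400-1
1.341,400-2
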