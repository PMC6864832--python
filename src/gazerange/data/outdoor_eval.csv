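number,situation,time,x_eye,y_eye,x_head,y_head,x_gaze,y_gaze,flag,judgment_error
1,Left,01:28,-30.8,0.6,-25.3,-20.2,-56.1,-19.6,Left,0
2,Right,02:05,28.9,14.4,9.8,3.6,38.7,18.0,Right,0
3,Right,02:26,7.4,4.0,32.4,30.1,39.8,34.1,Right,0
4,Right,02:50,40.7,46.8,21.4,24.0,62.1,70.8,Right,0
5,Left,02:52,-11.5,9.0,-32.6,-18.8,-44.1,-9.8,Left,0
6,Left,03:13,-10.5,-3.4,-33.8,-16.2,-44.3,-19.6,Left,0
7,Left,03:22,3.4,2.1,-123.9,-12.4,-120.5,-10.3,Left,0
8,Left,03:38,-28.6,4.6,-112.4,-18.7,-141.0,-14.1,Left,0
9,Left,03:54,6.3,4.2,-96.6,-16.7,-90.3,-12.5,Left,0
10,Left,03:56,5.2,2.1,14.6,6.8,-29.5,16.8,Right,1
11,Left,04:27,-41.9,8.9,-35.0,-15.7,-76.9,-6.7,Left,0
12,Front,04:41,-5.4,6.8,33.9,11.5,-31.2,18.8,Left,1
13,Straight,04:45,-5.6,8.7,4.8,-20.4,-0.8,-11.6,Front,0
14,Left,05:26,8.7,3.7,-95.6,-21.9,-86.9,-18.2,Left,0
15,Left,05:50,-21.6,-0.5,-40.8,-17.8,-62.4,-18.3,Left,0
16,Left,05:51,-21.3,1.8,-40.8,-17.8,-62.1,-16.0,Left,0
17,Right,06:46,33.7,-20.8,-1.4,-11.2,32.3,-32.1,Right,0
18,Left,06:51,-24.6,0.4,-29.9,-13.8,-54.5,-13.3,Left,0
19,Right,06:56,22.8,-1.4,34.6,15.8,57.4,14.4,Right,0
20,Straight,07:03,2.0,-4.0,-9.3,-17.4,-7.4,-21.4,Front,0
21,Left,07:07,-5.9,-5.6,-121.4,-13.9,-127.3,-19.5,Left,0
22,Left,07:48,-19.8,-4.2,-22.1,-25.9,-41.9,-30.1,Left,0
23,Left,08:28,2.4,0.9,-119.7,-14.8,-117.3,-13.9,Left,0
24,Right,09:15,24.3,3.4,5.3,18.8,29.6,22.2,Right,0
25,Right,09:50,59.8,50.7,-3.1,-12.7,56.7,38.0,Right,0
26,Straight,10:13,-0.1,5.0,5.3,15.9,5.2,20.9,Front,0
27,Left,10:20,2.2,-1.9,-40.4,-7.7,-38.2,-9.5,Left,0
28,Right,10:23,17.7,8.8,25.0,14.7,42.6,23.4,Right,0
29,Straight,10:30,-5.1,-2.4,18.6,12.8,13.5,10.4,Front,0
30,Right,10:35,10.0,4.2,33.3,16.3,43.2,20.4,Right,0
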