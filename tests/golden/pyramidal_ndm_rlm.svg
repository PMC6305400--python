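<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="800.0000" height="800.0000" viewBox="0 0 800.0000 800.0000">
<circle cx="400.0000" cy="400.0000" r="17.4159" fill="none" stroke="#000000" stroke-width="1.0000"/>
<circle cx="387.6851" cy="387.6851" r="4.3540" fill="#0000ff" stroke="none"/>
<line x1="387.6851" y1="387.6851" x2="320.1224" y2="320.1224" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 365.0922 292.5649 A 112.9639 112.9639 0 0 0 299.3484 348.7155" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="365.0922" y1="292.5649" x2="329.4898" y2="182.9920" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 364.3055 174.6335 A 228.1757 228.1757 0 0 0 296.4104 196.6940" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="364.3055" y1="174.6335" x2="344.3798" y2="48.8277" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="296.4104" y1="196.6940" x2="247.4176" y2="100.5402" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="299.3484" y1="348.7155" x2="210.7554" y2="303.5750" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 228.1695 275.1578 A 212.3942 212.3942 0 0 0 190.2207 366.7742" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="228.1695" y1="275.1578" x2="175.5669" y2="236.9398" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 203.8383 203.8383 A 277.4146 277.4146 0 0 0 152.8218 274.0564" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="203.8383" y1="203.8383" x2="152.5397" y2="152.5397" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="152.8218" y1="274.0564" x2="73.4039" y2="233.5910" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="190.2207" y1="366.7742" x2="106.6031" y2="353.5305" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="387.6851" cy="412.3149" r="4.3540" fill="#00ffff" stroke="none"/>
<line x1="387.6851" y1="412.3149" x2="312.2960" y2="487.7040" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 280.1942 432.1019 A 124.0321 124.0321 0 0 0 337.9839 507.4150" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="280.1942" y1="432.1019" x2="197.3167" y2="454.3088" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="337.9839" y1="507.4150" x2="282.6674" y2="603.2260" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 234.0666 565.9334 A 234.6652 234.6652 0 0 0 339.2642 626.6692" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="234.0666" y1="565.9334" x2="191.7498" y2="608.2502" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="339.2642" y1="626.6692" x2="302.6840" y2="763.1881" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="412.3149" cy="412.3149" r="4.3540" fill="#00ffff" stroke="none"/>
<line x1="412.3149" y1="412.3149" x2="472.1398" y2="472.1398" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 439.0418 494.2552 A 102.0211 102.0211 0 0 0 494.2552 439.0418" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="439.0418" y1="494.2552" x2="477.2279" y2="586.4446" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="494.2552" y1="439.0418" x2="551.3371" y2="462.6859" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="412.3149" cy="387.6851" r="4.3540" fill="#ff0000" stroke="none"/>
<line x1="412.3149" y1="387.6851" x2="464.0687" y2="335.9313" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 483.7098 365.3263 A 90.6068 90.6068 0 0 0 434.6737 316.2902" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="483.7098" y1="365.3263" x2="558.2264" y2="334.4605" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 567.9722 366.5882 A 171.2630 171.2630 0 0 0 542.4000 304.8514" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="567.9722" y1="366.5882" x2="616.4599" y2="356.9435" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="542.4000" y1="304.8514" x2="635.4601" y2="242.6706" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="434.6737" y1="316.2902" x2="468.9078" y2="233.6420" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 500.0386 250.2817 A 180.0646 180.0646 0 0 0 435.1289 223.3952" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="500.0386" y1="250.2817" x2="569.1256" y2="146.8857" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="435.1289" y1="223.3952" x2="454.6755" y2="125.1275" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
</svg>
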